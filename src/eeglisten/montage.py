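"""64-channel 10-20 montage and the six scalp subregions.

The channel list is the standard BioSemi 64-electrode layout (A1..B32
ordering).  Subregions group the scalp into frontal, central, left/right
temporal, parietal and occipital areas; the assignment table below follows
the usual lobe boundaries (Fp/AF/F rows frontal, FC/C rows central, lateral
FT/T/TP temporal split by hemisphere, CP/P rows parietal, PO/O rows
occipital) and can be overridden by passing an explicit mapping.
"""

from __future__ import annotations

import math

SUBREGIONS = (
    "frontal",
    "central",
    "left_temporal",
    "right_temporal",
    "parietal",
    "occipital",
)

#: BioSemi 64-channel labels, A1..B32 order.
BIOSEMI64 = (
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7",
    "FC5", "FC3", "FC1", "C1", "C3", "C5", "T7", "TP7",
    "CP5", "CP3", "CP1", "P1", "P3", "P5", "P7", "P9",
    "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz",
    "Fpz", "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4",
    "F6", "F8", "FT8", "FC6", "FC4", "FC2", "FCz", "Cz",
    "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4", "CP2",
    "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
)

#: Auxiliary (non-scalp) labels used by the synthetic cohort / recordings.
AUX_LABELS = ("Nose", "Sound")


def _assign(label: str) -> str:
    """Subregion for one 10-20 label (scalp channels only)."""
    lateral_temporal = {"FT7", "T7", "TP7", "FT8", "T8", "TP8"}
    if label in lateral_temporal:
        return "left_temporal" if label.endswith("7") else "right_temporal"
    if label.startswith(("Fp", "AF")) or (
        label.startswith("F") and not label.startswith("FC")
    ):
        return "frontal"
    if label.startswith(("FC", "C")) and not label.startswith("CP"):
        return "central"
    if label.startswith(("CP", "P")) and not label.startswith("PO"):
        return "parietal"
    if label.startswith(("PO", "O", "I")):
        return "occipital"
    raise KeyError(f"no subregion rule for channel {label!r}")


def default_subregion_map(labels=BIOSEMI64, require_all: bool = True) -> dict[str, str]:
    """Map every scalp label to exactly one of the six subregions.

    Parameters
    ----------
    labels : iterable of str
        Scalp channel labels (10-20 names). Auxiliary labels (nose
        reference, sound channels, EOG/mastoids) must not be included.
    require_all : bool
        When true (default), raise if any subregion ends up empty.
    """
    mapping = {lab: _assign(lab) for lab in labels}
    if require_all:
        missing = set(SUBREGIONS) - set(mapping.values())
        if missing:
            raise ValueError(f"subregions without channels: {sorted(missing)}")
    return mapping


def validate_subregion_map(mapping: dict[str, str], labels) -> None:
    """Check that ``mapping`` partitions ``labels`` into six non-empty groups."""
    labels = list(labels)
    unmapped = [lab for lab in labels if lab not in mapping]
    if unmapped:
        raise ValueError(f"channels without subregion: {unmapped}")
    bad = {lab: sr for lab, sr in mapping.items() if sr not in SUBREGIONS}
    if bad:
        raise ValueError(f"unknown subregions: {bad}")
    counts = {sr: 0 for sr in SUBREGIONS}
    for lab in labels:
        counts[mapping[lab]] += 1
    empty = [sr for sr, c in counts.items() if c == 0]
    if empty:
        raise ValueError(f"empty subregions: {empty}")


# Approximate 2-D positions (azimuthal-equidistant projection, nose up,
# left ear left) used only for topographic plotting.
def positions_2d(labels=BIOSEMI64) -> dict[str, tuple[float, float]]:
    # (theta from vertex in degrees, phi counterclockwise from right ear)
    sph = _SPHERICAL
    out = {}
    for lab in labels:
        theta, phi = sph[lab]
        r = theta / 90.0
        out[lab] = (r * math.cos(math.radians(phi)),
                    r * math.sin(math.radians(phi)))
    return out


_SPHERICAL = {
    # midline
    "Fpz": (90, 90), "AFz": (67, 90), "Fz": (45, 90), "FCz": (22, 90),
    "Cz": (0, 0), "CPz": (22, -90), "Pz": (45, -90), "POz": (67, -90),
    "Oz": (90, -90), "Iz": (112, -90),
    # frontal pole / anterior-frontal
    "Fp1": (90, 108), "Fp2": (90, 72),
    "AF7": (90, 126), "AF3": (74, 113), "AF4": (74, 67), "AF8": (90, 54),
    # frontal row
    "F7": (90, 144), "F5": (74, 139), "F3": (60, 129), "F1": (49, 112),
    "F2": (49, 68), "F4": (60, 51), "F6": (74, 41), "F8": (90, 36),
    # fronto-central / fronto-temporal
    "FT7": (90, 162), "FC5": (69, 157), "FC3": (50, 148), "FC1": (32, 125),
    "FC2": (32, 55), "FC4": (50, 32), "FC6": (69, 23), "FT8": (90, 18),
    # central / temporal
    "T7": (90, 180), "C5": (68, 180), "C3": (45, 180), "C1": (23, 180),
    "C2": (23, 0), "C4": (45, 0), "C6": (68, 0), "T8": (90, 0),
    # centro-parietal / temporo-parietal
    "TP7": (90, -162), "CP5": (69, -157), "CP3": (50, -148), "CP1": (32, -125),
    "CP2": (32, -55), "CP4": (50, -32), "CP6": (69, -23), "TP8": (90, -18),
    # parietal
    "P9": (112, -144), "P7": (90, -144), "P5": (74, -139), "P3": (60, -129),
    "P1": (49, -112), "P2": (49, -68), "P4": (60, -51), "P6": (74, -41),
    "P8": (90, -36), "P10": (112, -36),
    # parieto-occipital / occipital
    "PO7": (90, -126), "PO3": (74, -113), "PO4": (74, -67), "PO8": (90, -54),
    "O1": (90, -108), "O2": (90, -72),
}
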