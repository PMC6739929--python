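"""Canonical registry of the 352 radiomic feature names.

The registry fixes the column set and order of every feature table produced
by this package.  Names follow the MaZda conventions used in the breast-MRI
texture-analysis literature: co-occurrence features are ``S(dx,dy)Stat``
with the pixel offset spelled into the name, run-length features carry a
direction prefix (``Horzl_``, ``Vertl_``, ``45dgr_``, ``135dr_``), wavelet
energies are ``WavEnSB_s-k`` and geometry features are ``Geo*``.

Family sizes: HIS 9, COM 220, RLM 20, GRA 5, ARM 5, WAV 20, GEO 73
(total 352).
"""

from __future__ import annotations

import json
import re

HIS_NAMES = (
    "Mean",
    "Variance",
    "Skewness",
    "Kurtosis",
    "Perc.01%",
    "Perc.10%",
    "Perc.50%",
    "Perc.90%",
    "Perc.99%",
)

#: Haralick-type statistics computed on every co-occurrence matrix.
COM_STATS = (
    "AngScMom",
    "Contrast",
    "Correlat",
    "SumOfSqs",
    "InvDfMom",
    "SumAverg",
    "SumVarnc",
    "SumEntrp",
    "Entropy",
    "DifVarnc",
    "DifEntrp",
)

#: Pixel offsets (dx, dy) for the co-occurrence matrices; the y axis points
#: down (row index), so (d, -d) is the 45-degree diagonal and (d, d) the
#: 135-degree diagonal.  4 orientations x 5 distances = 20 offsets.
COM_OFFSETS = tuple(
    (dx, dy)
    for d in range(1, 6)
    for (dx, dy) in ((d, 0), (0, d), (d, d), (d, -d))
)

RLM_DIRECTIONS = ("Horzl", "Vertl", "45dgr", "135dr")
RLM_STATS = ("ShrtREmp", "LngREmph", "GLevNonU", "RLNonUni", "Fraction")

GRA_NAMES = ("GrMean", "GrVariance", "GrSkewness", "GrKurtosis", "GrNonZeros")
ARM_NAMES = ("Teta1", "Teta2", "Teta3", "Teta4", "Sigma")

WAV_SUBBANDS = ("LL", "LH", "HL", "HH")
WAV_SCALES = (1, 2, 3, 4, 5)


def com_name(dx: int, dy: int, stat: str) -> str:
    return f"S({dx},{dy}){stat}"


_COM_RE = re.compile(r"^S\((-?\d+),(-?\d+)\)([A-Za-z]+)$")


def parse_com_name(name: str) -> tuple[int, int, str] | None:
    """Return (dx, dy, stat) for an ``S(dx,dy)Stat`` name, else None."""
    m = _COM_RE.match(name)
    if m is None:
        return None
    dx, dy, stat = int(m.group(1)), int(m.group(2)), m.group(3)
    if (dx, dy) in COM_OFFSETS and stat in COM_STATS:
        return dx, dy, stat
    return None


def com_names() -> list[str]:
    return [com_name(dx, dy, s) for (dx, dy) in COM_OFFSETS for s in COM_STATS]


def rlm_names() -> list[str]:
    return [f"{d}_{s}" for d in RLM_DIRECTIONS for s in RLM_STATS]


def wav_names() -> list[str]:
    return [f"WavEn{sb}_s-{k}" for k in WAV_SCALES for sb in WAV_SUBBANDS]


# Geometry registry: morphometric descriptors of the binary lesion mask.
# GeoW1..GeoW7 are the normalized central moments (eta20, eta11, eta02,
# eta30, eta21, eta12, eta03); GeoW8..GeoW14 the seven Hu moment
# invariants; GeoE1..GeoE12 the first twelve harmonic amplitudes of the
# centroid radius function r(phi), normalized by its mean.
GEO_NAMES = (
    "GeoArea",
    "GeoPerimeter",
    "GeoCircularity",
    "GeoCompactness",
    "GeoPerimArea",
    "GeoNormPerim",
    "GeoEquivDiam",
    "GeoExtent",
    "GeoEccentricity",
    "GeoOrientation",
    "GeoMajorAxis",
    "GeoMinorAxis",
    "GeoAxisRatio",
    "GeoFeretMax",
    "GeoFeretMin",
    "GeoFeret0",
    "GeoFeret45",
    "GeoFeret90",
    "GeoFeret135",
    "GeoFeretMean",
    "GeoElongation",
    "GeoBBoxW",
    "GeoBBoxH",
    "GeoBBoxAspect",
    "GeoRadMean",
    "GeoRadSD",
    "GeoRadCV",
    "GeoRadMax",
    "GeoRadMin",
    "GeoRadSpan",
    "GeoRadSkewness",
    "GeoRadKurtosis",
    "GeoRadEntropy",
    "GeoRadAreaRatio",
    "GeoRadZeroCross",
    "GeoConvexity",
    "GeoConvPerim",
    "GeoDefectArea",
    "GeoSymRot180",
    "GeoSymHorz",
    "GeoSymVert",
    "GeoInscribedR",
    "GeoDistMean",
    "GeoDistSD",
    "GeoThickness",
    *[f"GeoW{i}" for i in range(1, 15)],
    *[f"GeoE{i}" for i in range(1, 13)],
    "GeoELow",
    "GeoEHigh",
)

FAMILY_SIZES = {
    "HIS": 9,
    "COM": 220,
    "RLM": 20,
    "GRA": 5,
    "ARM": 5,
    "WAV": 20,
    "GEO": 73,
}


def family_names(family: str) -> list[str]:
    """Registry names of one feature family, in canonical order."""
    if family == "HIS":
        return list(HIS_NAMES)
    if family == "COM":
        return com_names()
    if family == "RLM":
        return rlm_names()
    if family == "GRA":
        return list(GRA_NAMES)
    if family == "ARM":
        return list(ARM_NAMES)
    if family == "WAV":
        return wav_names()
    if family == "GEO":
        return list(GEO_NAMES)
    raise KeyError(f"unknown feature family: {family!r}")


def all_names() -> list[str]:
    """All 352 feature names in canonical registry order."""
    names: list[str] = []
    for fam in ("HIS", "COM", "RLM", "GRA", "ARM", "WAV", "GEO"):
        names.extend(family_names(fam))
    return names


def family_of(name: str) -> str:
    """Feature family a registry name belongs to."""
    if name in HIS_NAMES:
        return "HIS"
    if parse_com_name(name) is not None:
        return "COM"
    if name in rlm_names():
        return "RLM"
    if name in GRA_NAMES:
        return "GRA"
    if name in ARM_NAMES:
        return "ARM"
    if name.startswith("WavEn") and name in wav_names():
        return "WAV"
    if name in GEO_NAMES:
        return "GEO"
    raise KeyError(f"not a registry feature name: {name!r}")


def export_registry(path) -> None:
    """Write the registry (per-family name lists) as JSON."""
    payload = {fam: family_names(fam) for fam in FAMILY_SIZES}
    payload["all"] = all_names()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


_ALL = all_names()
assert len(_ALL) == 352 and len(set(_ALL)) == 352
assert [len(family_names(f)) for f in FAMILY_SIZES] == list(FAMILY_SIZES.values())
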