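"""Backbone dynamics (heteronuclear NOE) and PRE proximity profiling.

The steady-state 1H-15N heteronuclear NOE enhancement is the intensity ratio
I_sat/I_ref between spectra recorded with and without proton saturation;
negative values report sub-nanosecond backbone flexibility.  PRE profiles are
per-residue intensity ratios I_para/I_dia between spectra acquired with a
paramagnetic (MTSL) and diamagnetic (dMTSL) spin label on the partner; low
ratios report proximity of the amide to the unpaired electron (r^-6
broadening, conventionally interpreted out to ~20 A).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._tables import BACKBONE_ATOMS
from .io import StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "HetNOERecord",
    "PRERecord",
    "PREProfile",
    "ProximityReport",
    "compute_hetnoe",
    "classify_dynamics",
    "compute_pre_profile",
    "flag_proximal_residues",
    "label_site_coordinate",
]


@dataclass(frozen=True)
class HetNOERecord:
    residue_number: int
    I_sat: float
    I_ref: float
    noe: float
    noe_err: float | None = None


@dataclass(frozen=True)
class PRERecord:
    residue_number: int
    I_para: float
    I_dia: float
    ratio: float
    proximal: bool


@dataclass
class PREProfile:
    records: list[PRERecord]
    label_site: int
    cutoff_distance: float = 20.0

    def __post_init__(self) -> None:
        if self.cutoff_distance <= 0:
            raise ValueError("cutoff_distance must be > 0")
        self.records = sorted(self.records, key=lambda r: r.residue_number)

    def proximal_residues(self) -> list[int]:
        return [r.residue_number for r in self.records if r.proximal]


def _to_intensity_map(table) -> dict[int, float]:
    if isinstance(table, dict):
        return {int(k): float(v) for k, v in table.items()}
    df = pd.DataFrame(table)
    return {int(r): float(v) for r, v in zip(df["residue"], df["intensity"])}


def compute_hetnoe(sat, ref, sigma_sat: float | None = None,
                   sigma_ref: float | None = None
                   ) -> tuple[list[HetNOERecord], list[int]]:
    """Per-residue NOE enhancement I_sat/I_ref.

    ``sat``/``ref`` are dicts ``residue -> intensity`` or frames with columns
    ``residue, intensity``.  Returns (records, unmatched residues).  When the
    spectral noise levels are given, the ratio error is propagated; otherwise
    ``noe_err`` is left None rather than fabricated.
    """
    s, r = _to_intensity_map(sat), _to_intensity_map(ref)
    shared = sorted(set(s) & set(r))
    unmatched = sorted(set(s) ^ set(r))
    records = []
    for res in shared:
        if r[res] == 0:
            raise ValueError(f"reference intensity is zero for residue {res}")
        noe = s[res] / r[res]
        err = None
        if sigma_sat is not None and sigma_ref is not None and s[res] != 0:
            err = abs(noe) * np.hypot(sigma_sat / s[res], sigma_ref / r[res])
            err = float(abs(err))
        records.append(HetNOERecord(res, s[res], r[res], noe, err))
    return records, unmatched


def classify_dynamics(records: list[HetNOERecord], rigid_threshold: float = 0.65,
                      flexible_threshold: float = 0.0) -> dict[int, str]:
    """Partition residues into flexibility classes by NOE value.

    noe < flexible_threshold -> "highly flexible"; below rigid_threshold ->
    "partially ordered"; otherwise "rigid".
    """
    if not flexible_threshold < rigid_threshold:
        raise ValueError("need flexible_threshold < rigid_threshold")
    out = {}
    for rec in records:
        if rec.noe < flexible_threshold:
            out[rec.residue_number] = "highly flexible"
        elif rec.noe < rigid_threshold:
            out[rec.residue_number] = "partially ordered"
        else:
            out[rec.residue_number] = "rigid"
    return out


def compute_pre_profile(para, dia, label_site: int,
                        broadening_threshold: float = 0.7,
                        cutoff_distance: float = 20.0,
                        mode: str = "absolute") -> PREProfile:
    """Per-residue paramagnetic/diamagnetic intensity ratios.

    Residues present in the diamagnetic list but vanished from the
    paramagnetic spectrum (fully broadened) get ratio 0 and are flagged
    proximal.  ``mode="mean_sd"`` flags residues below (mean - 1 SD) of the
    ratio profile instead of the absolute threshold.
    """
    p, d = _to_intensity_map(para), _to_intensity_map(dia)
    records: list[PRERecord] = []
    raw: dict[int, tuple[float, float]] = {}
    for res in sorted(d):
        if d[res] <= 0:
            raise ValueError(f"diamagnetic intensity <= 0 for residue {res}")
        if res not in p:
            logger.warning(
                "residue %d absent from paramagnetic spectrum: ratio 0, proximal", res
            )
            raw[res] = (0.0, d[res])
            continue
        ip = p[res]
        if ip < 0:
            logger.warning("residue %d: negative paramagnetic intensity clamped to 0", res)
            ip = 0.0
        raw[res] = (ip, d[res])
    ratios = {res: ip / idia for res, (ip, idia) in raw.items()}
    if mode == "mean_sd":
        vals = np.array(list(ratios.values()))
        thr = float(vals.mean() - vals.std(ddof=0))
    elif mode == "absolute":
        thr = broadening_threshold
    else:
        raise ValueError(f"unknown mode {mode!r}")
    for res, (ip, idia) in raw.items():
        records.append(PRERecord(res, ip, idia, ratios[res], ratios[res] < thr))
    return PREProfile(records, label_site, cutoff_distance)


def label_site_coordinate(structure: StructureModel, residue_number: int) -> np.ndarray:
    """Representative position of a spin label attached at ``residue_number``.

    The nitroxide extends from the mutated side chain, so the representative
    atom is the side-chain heavy atom farthest from CA, falling back to CB and
    then CA for short or missing side chains.
    """
    m = structure.residue_mask(residue_number)
    if not m.any():
        raise KeyError(f"residue {residue_number} not in structure")
    names = structure.atom_names[m]
    coords = structure.coords[m]
    side = [i for i, n in enumerate(names) if n not in BACKBONE_ATOMS]
    if side and "CA" in names:
        ca = coords[list(names).index("CA")]
        dists = [np.linalg.norm(coords[i] - ca) for i in side]
        return coords[side[int(np.argmax(dists))]]
    for fallback in ("CB", "CA"):
        if fallback in names:
            return coords[list(names).index(fallback)]
    return coords[0]


@dataclass
class ProximityReport:
    """Agreement between PRE proximity flags and structure distances."""

    distances: dict[int, float]          # proximal residue -> distance to label (A)
    fraction_within: float | None       # None when no proximal residues
    violations: list[int] = field(default_factory=list)
    cutoff_distance: float = 20.0


def flag_proximal_residues(profile: PREProfile, structure: StructureModel,
                           label_structure_site: int,
                           offset: int = 0) -> ProximityReport:
    """Check proximal-flagged residues against amide-N-to-label distances.

    ``offset`` maps profile numbering onto structure numbering
    (structure = profile + offset).  Residues flagged proximal but farther
    than the profile's cutoff are listed as violations.
    """
    label_xyz = label_site_coordinate(structure, label_structure_site)
    distances: dict[int, float] = {}
    violations: list[int] = []
    for res in profile.proximal_residues():
        try:
            n_xyz = structure.atom_coord(res + offset, "N")
        except KeyError as exc:
            raise KeyError(
                f"proximal residue {res} (structure {res + offset}) missing amide N"
            ) from exc
        d = float(np.linalg.norm(n_xyz - label_xyz))
        distances[res] = d
        if d > profile.cutoff_distance:
            violations.append(res)
    frac = None
    if distances:
        frac = 1.0 - len(violations) / len(distances)
    return ProximityReport(distances, frac, violations, profile.cutoff_distance)
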