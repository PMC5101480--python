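"""Solvent accessibility and CSP-driven ambiguous interaction restraints.

Active residues for data-driven docking are those both perturbed in the CSP
experiment (combined shift change above a ppm cutoff) and solvent exposed
(relative side-chain-inclusive accessibility above a percentage cutoff);
accessible residues juxtaposed to actives become passive.  Each active residue
is restrained ambiguously against every active and passive residue of the
partner, written as CNS-syntax ``assign`` statements.

SASA uses the Shrake-Rupley rolling-probe construction with a deterministic
Fibonacci sphere point set, so results are exactly reproducible for a fixed
``n_points``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._tables import MAX_ASA_TIEN_THEORETICAL
from .io import StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "SASAResult",
    "RestraintSet",
    "fibonacci_sphere",
    "compute_sasa",
    "relative_sasa",
    "select_air_residues",
    "ActivePassive",
    "write_air_restraints",
    "parse_air_restraints",
]


@dataclass
class SASAResult:
    per_atom: np.ndarray                      # A^2, aligned with structure atoms
    per_residue: dict[int, float]             # residue -> A^2
    residue_names: dict[int, str]             # residue -> three-letter code
    probe_radius: float
    n_points: int
    relative: dict[int, float] = field(default_factory=dict)  # residue -> %

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden-angle spiral).

    The set is made antipodally symmetric (odd ``n`` is rounded up): a point
    and its negation are both present, so two identical atoms occlude each
    other identically and symmetric configurations get exactly equal SASA.
    """
    m = (n + 1) // 2
    i = np.arange(m, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    # spiral over the upper hemisphere only, then mirror
    z = 1.0 - (i + 0.5) / m
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    upper = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return np.concatenate([upper, -upper])


def compute_sasa(structure: StructureModel, probe_radius: float = 1.4,
                 n_points: int = 960) -> SASAResult:
    """Shrake-Rupley solvent-accessible surface area.

    For each atom, test points on the expanded sphere (r_vdw + probe) are kept
    if they fall outside every neighbour's expanded sphere; the accessible
    fraction times the sphere area is the atom's SASA.  Deterministic for a
    fixed point count.
    """
    if len(structure) == 0:
        raise ValueError("empty structure")
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    if n_points < 92:
        raise ValueError("n_points must be >= 92 for a usable sphere sampling")
    coords = structure.coords
    radii = structure.radii + probe_radius
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    rmax = radii.max()
    per_atom = np.empty(len(coords))
    for i in range(len(coords)):
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + rmax)
                     if j != i]
        nb = [j for j in neighbors
              if np.linalg.norm(coords[j] - coords[i]) < radii[i] + radii[j]]
        for j in nb:
            if np.linalg.norm(coords[j] - coords[i]) == 0.0:
                raise ValueError(
                    f"atoms {i} and {j} coincide: overlapping identical atoms"
                )
        pts = coords[i] + radii[i] * sphere
        accessible = np.ones(len(sphere), dtype=bool)
        for j in nb:
            accessible &= np.sum((pts - coords[j]) ** 2, axis=1) > radii[j] ** 2
            if not accessible.any():
                break
        per_atom[i] = accessible.mean() * 4.0 * np.pi * radii[i] ** 2

    per_residue: dict[int, float] = {}
    residue_names: dict[int, str] = {}
    for res in np.unique(structure.residue_numbers):
        m = structure.residue_numbers == res
        per_residue[int(res)] = float(per_atom[m].sum())
        residue_names[int(res)] = str(structure.residue_names[m][0])
    return SASAResult(per_atom, per_residue, residue_names, probe_radius, n_points)


def relative_sasa(result: SASAResult,
                  reference_table: dict[str, float] | None = None) -> dict[int, float]:
    """Per-residue accessibility as % of the reference maximum ASA.

    Values above 100% (typical for chain termini) are logged, never clipped.
    """
    table = reference_table if reference_table is not None else MAX_ASA_TIEN_THEORETICAL
    out: dict[int, float] = {}
    for res, sasa in result.per_residue.items():
        name = result.residue_names[res].upper()
        if name not in table:
            raise KeyError(f"residue type {name!r} absent from reference max-ASA table")
        rel = 100.0 * sasa / table[name]
        if rel > 100.0:
            logger.info("residue %d relative accessibility %.1f%% > 100%% (terminus?)",
                        res, rel)
        out[res] = rel
    result.relative = out
    return out


# ---------------------------------------------------------------------------
# restraint selection

@dataclass
class ActivePassive:
    """Active/passive designation for one molecule."""

    active: set[int]
    passive: set[int]

    def __post_init__(self) -> None:
        if self.active & self.passive:
            raise ValueError("active and passive sets overlap")
        if not self.active:
            raise ValueError("at least one active residue required")


@dataclass
class RestraintSet:
    active_A: set[int]
    passive_A: set[int]
    active_B: set[int]
    passive_B: set[int]
    distance_bounds: tuple[float, float, float] = (2.0, 2.0, 0.0)  # d, d-minus, d-plus

    def __post_init__(self) -> None:
        if self.active_A & self.passive_A or self.active_B & self.passive_B:
            raise ValueError("active and passive sets overlap")
        if not self.active_A or not self.active_B:
            raise ValueError("each molecule needs at least one active residue")


def select_air_residues(csp_perturbed, rel_sasa: dict[int, float],
                        structure: StructureModel,
                        csp_threshold: float = 0.10,
                        sasa_threshold: float = 45.0,
                        passive_radius: float = 6.5) -> ActivePassive:
    """Active/passive selection for one molecule.

    ``csp_perturbed`` is either a residue set (already thresholded) or a
    mapping residue -> delta_av to which ``csp_threshold`` is applied.
    Active = perturbed and relative accessibility > ``sasa_threshold``;
    passive = other accessible residues with any heavy atom within
    ``passive_radius`` (A) of any active-residue heavy atom.
    """
    if csp_threshold <= 0 or sasa_threshold <= 0:
        raise ValueError("thresholds must be > 0")
    if isinstance(csp_perturbed, dict):
        perturbed = {r for r, v in csp_perturbed.items() if v > csp_threshold}
    else:
        perturbed = set(csp_perturbed)
    accessible = {r for r, v in rel_sasa.items() if v > sasa_threshold}
    active = perturbed & accessible
    if not active:
        raise ValueError(
            "no active residues: every perturbed residue fails the accessibility "
            "cutoff (or vice versa); review the CSP and SASA thresholds"
        )
    active_mask = np.isin(structure.residue_numbers, sorted(active))
    tree = cKDTree(structure.coords[active_mask])
    passive = set()
    for res in accessible - active:
        m = structure.residue_mask(res)
        if not m.any():
            continue
        d, _ = tree.query(structure.coords[m], k=1)
        if np.min(d) <= passive_radius:
            passive.add(res)
    return ActivePassive(active=active, passive=passive)


# ---------------------------------------------------------------------------
# CNS-syntax AIR writer / parser

def _selection(res: int, segid: str) -> str:
    return f"(resid {res} and segid {segid})"


def write_air_restraints(rset: RestraintSet, path,
                         segid_A: str = "A", segid_B: str = "B") -> None:
    """Emit ambiguous distance restraints in CNS ``assign`` syntax.

    One block per active residue, restrained against the partner's active plus
    passive residues; bounds are written as ``target lower-margin upper-margin``
    (default 2.0 2.0 0.0, the standard protocol's effective-distance bounds).
    """
    d, dm, dp = rset.distance_bounds
    lines = ["! Ambiguous interaction restraints generated by clampmap"]
    for seg, actives, partner_seg, partner in (
        (segid_A, rset.active_A, segid_B, sorted(rset.active_B | rset.passive_B)),
        (segid_B, rset.active_B, segid_A, sorted(rset.active_A | rset.passive_A)),
    ):
        for res in sorted(actives):
            lines.append(f"assign {_selection(res, seg)}")
            lines.append("       (")
            for k, tres in enumerate(partner):
                prefix = "        " if k == 0 else "     or "
                lines.append(f"{prefix}{_selection(tres, partner_seg)}")
            lines.append(f"       ) {d:.1f} {dm:.1f} {dp:.1f}")
            lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


_ASSIGN_RE = re.compile(
    r"assign\s*\(resid\s+(\d+)\s+and\s+segid\s+(\w+)\)(.*?)\)\s*"
    r"([\d.]+)\s+([\d.]+)\s+([\d.]+)",
    re.DOTALL,
)
_SEL_RE = re.compile(r"\(resid\s+(\d+)\s+and\s+segid\s+(\w+)\)")


def parse_air_restraints(path, segid_A: str = "A", segid_B: str = "B") -> RestraintSet:
    """Re-parse a written AIR table back into a `RestraintSet`."""
    with open(path) as fh:
        text = fh.read()
    active = {segid_A: set(), segid_B: set()}
    targets = {segid_A: set(), segid_B: set()}
    bounds = (2.0, 2.0, 0.0)
    for m in _ASSIGN_RE.finditer(text):
        res, seg, body = int(m.group(1)), m.group(2), m.group(3)
        bounds = (float(m.group(4)), float(m.group(5)), float(m.group(6)))
        if seg not in active:
            raise ValueError(f"unexpected segid {seg!r} in {path}")
        active[seg].add(res)
        for sm in _SEL_RE.finditer(body):
            targets[_other(seg, segid_A, segid_B)].add(int(sm.group(1)))
    if not active[segid_A] or not active[segid_B]:
        raise ValueError(f"no assign blocks for both molecules in {path}")
    return RestraintSet(
        active_A=active[segid_A],
        passive_A=targets[segid_A] - active[segid_A],
        active_B=active[segid_B],
        passive_B=targets[segid_B] - active[segid_B],
        distance_bounds=bounds,
    )


def _other(seg: str, a: str, b: str) -> str:
    return b if seg == a else a
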