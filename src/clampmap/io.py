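"""Readers for assigned peak lists and PDB structures, and titration alignment.

Peak lists are consumed as assigned tabular files (the effective input of a
chemical-shift-perturbation study: spectral processing and assignment happen
upstream).  Two dialects are supported:

``tsv``
    Five tab-separated columns: assignment label, residue number, 15N shift
    (ppm), 1H shift (ppm), intensity.  Lines starting with ``#`` and a header
    row are ignored.

``sparky``
    The Sparky "lt" peak-list layout: ``Assignment  w1  w2  [Data Height]``
    with assignments such as ``M102N-H`` (w1 = 15N, w2 = 1H).

Structures are read with gemmi; only heavy atoms of the requested chain are
kept, alternate locations are resolved to the highest-occupancy conformer, and
element-based van der Waals radii are attached (see `_tables.VDW_RADII`).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

from ._tables import THREE_TO_ONE, vdw_radius

logger = logging.getLogger(__name__)

__all__ = [
    "AssignedPeak",
    "TitrationPoint",
    "TitrationSeries",
    "StructureModel",
    "Trajectory",
    "read_peaklist",
    "write_peaklist",
    "read_structure",
    "match_titration_peaks",
]


@dataclass(frozen=True)
class AssignedPeak:
    """One assigned amide cross-peak.

    Shifts are in ppm; intensity is a signed peak height in arbitrary units.
    """

    residue_number: int
    residue_type: str
    shift_H: float
    shift_N: float
    intensity: float | None = None

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise ValueError(f"residue_number must be >= 1, got {self.residue_number}")
        if not (-2.0 <= self.shift_H <= 15.0):
            raise ValueError(f"shift_H {self.shift_H} ppm outside [-2, 15]")
        if np.isfinite(self.shift_N) and not (90.0 <= self.shift_N <= 140.0):
            raise ValueError(f"shift_N {self.shift_N} ppm outside [90, 140]")


@dataclass
class TitrationPoint:
    """All peaks observed at one ligand:protein molar ratio."""

    molar_ratio: float
    labelled_conc: float  # total labelled-protein concentration, uM
    ligand_conc: float    # total unlabelled-partner concentration, uM
    peaks: list[AssignedPeak] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.labelled_conc <= 0:
            raise ValueError("labelled_conc must be > 0")
        if self.molar_ratio < 0:
            raise ValueError("molar_ratio must be >= 0")
        expected = self.molar_ratio * self.labelled_conc
        scale = max(abs(expected), abs(self.ligand_conc), 1.0)
        if abs(self.ligand_conc - expected) > 1e-6 * scale:
            raise ValueError(
                f"ligand_conc {self.ligand_conc} inconsistent with "
                f"molar_ratio x labelled_conc = {expected}"
            )

    def peak_map(self) -> dict[int, AssignedPeak]:
        out: dict[int, AssignedPeak] = {}
        for p in self.peaks:
            if p.residue_number in out:
                raise ValueError(
                    f"duplicate residue {p.residue_number} at ratio {self.molar_ratio}"
                )
            out[p.residue_number] = p
        return out


@dataclass
class TitrationSeries:
    """Ordered titration points; the first point is the free state (ratio 0)."""

    points: list[TitrationPoint]
    observed_nucleus: str = "15N-labelled"

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("titration series needs at least one point")
        ratios = [p.molar_ratio for p in self.points]
        if ratios[0] != 0:
            raise ValueError("first titration point must be the free state (ratio 0)")
        if any(b <= a for a, b in zip(ratios, ratios[1:])):
            raise ValueError("molar ratios must be strictly increasing")

    @property
    def ratios(self) -> list[float]:
        return [p.molar_ratio for p in self.points]


@dataclass
class StructureModel:
    """Heavy atoms of one chain, as parallel arrays."""

    atom_names: np.ndarray      # str array
    residue_numbers: np.ndarray  # int array
    residue_names: np.ndarray   # three-letter codes
    chain_ids: np.ndarray
    elements: np.ndarray
    coords: np.ndarray          # (n, 3) A
    radii: np.ndarray           # vdW radii, A

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.radii <= 0):
            raise ValueError("van der Waals radii must be > 0")

    def __len__(self) -> int:
        return len(self.coords)

    def residue_mask(self, residue_number: int) -> np.ndarray:
        return self.residue_numbers == residue_number

    def atom_coord(self, residue_number: int, atom_name: str) -> np.ndarray:
        m = self.residue_mask(residue_number) & (self.atom_names == atom_name)
        if not m.any():
            raise KeyError(f"atom {atom_name} of residue {residue_number} not in structure")
        return self.coords[m][0]

    def residue_numbers_unique(self) -> np.ndarray:
        return np.unique(self.residue_numbers)


# ---------------------------------------------------------------------------
# peak lists

_SPARKY_ASSIGN = re.compile(r"^([A-Za-z])?(\d+)N(?:H)?-?H?N?$")


def _parse_sparky_assignment(label: str) -> tuple[int, str]:
    """Parse labels like ``M102N-H`` / ``A101N-HN`` / ``102N-H``."""
    m = _SPARKY_ASSIGN.match(label.strip())
    if not m:
        raise ValueError(f"unparseable assignment {label!r}")
    aa = m.group(1) or "X"
    return int(m.group(2)), aa.upper()


def read_peaklist(path, dialect: str = "tsv") -> list[AssignedPeak]:
    """Read one assigned peak list.

    Rows that fail to parse are skipped with a logged warning naming the line;
    a file with zero parseable rows is a hard error.
    """
    if dialect not in ("tsv", "sparky"):
        raise ValueError(f"unsupported dialect {dialect!r}")
    peaks: list[AssignedPeak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                if dialect == "tsv":
                    parts = line.split("\t")
                    if len(parts) < 4:
                        raise ValueError("expected >= 4 tab-separated fields")
                    label, resnum, shift_n, shift_h = parts[:4]
                    intensity = float(parts[4]) if len(parts) > 4 and parts[4] != "" else None
                    aa = label.strip()[:1].upper() if label.strip() else "X"
                    if aa not in THREE_TO_ONE.values():
                        aa = "X"
                    peak = AssignedPeak(
                        residue_number=int(resnum),
                        residue_type=aa,
                        shift_H=float(shift_h),
                        shift_N=float(shift_n),
                        intensity=intensity,
                    )
                else:  # sparky
                    parts = line.split()
                    if parts[0].lower() == "assignment":
                        continue
                    resnum, aa = _parse_sparky_assignment(parts[0])
                    shift_n, shift_h = float(parts[1]), float(parts[2])
                    intensity = float(parts[3]) if len(parts) > 3 else None
                    peak = AssignedPeak(resnum, aa, shift_h, shift_n, intensity)
            except (ValueError, IndexError) as exc:
                if dialect == "tsv" and _looks_like_header(line):
                    continue
                logger.warning("%s line %d skipped: %s", path, lineno, exc)
                continue
            peaks.append(peak)
    if not peaks:
        raise ValueError(f"no parseable peaks in {path}")
    return peaks


def _looks_like_header(line: str) -> bool:
    fields = line.split("\t")
    return len(fields) >= 4 and not any(_is_float(f) for f in fields)


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_peaklist(peaks: list[AssignedPeak], path, dialect: str = "tsv") -> None:
    """Write peaks in a format `read_peaklist` accepts (round-trip safe)."""
    with open(path, "w") as fh:
        if dialect == "tsv":
            fh.write("assignment\tresidue\tshift_N\tshift_H\tintensity\n")
            for p in sorted(peaks, key=lambda q: q.residue_number):
                inten = "" if p.intensity is None else f"{p.intensity:.6f}"
                fh.write(
                    f"{p.residue_type}{p.residue_number}\t{p.residue_number}\t"
                    f"{p.shift_N:.6f}\t{p.shift_H:.6f}\t{inten}\n"
                )
        elif dialect == "sparky":
            fh.write("     Assignment         w1         w2   Data Height\n\n")
            for p in sorted(peaks, key=lambda q: q.residue_number):
                inten = "" if p.intensity is None else f"{p.intensity:14.3f}"
                fh.write(
                    f"{p.residue_type}{p.residue_number}N-H "
                    f"{p.shift_N:10.4f} {p.shift_H:10.4f}{inten}\n"
                )
        else:
            raise ValueError(f"unsupported dialect {dialect!r}")


# ---------------------------------------------------------------------------
# structures

def read_structure(path, chain: str) -> StructureModel:
    """Load heavy atoms of one chain from a PDB file.

    Alternate locations collapse to the highest-occupancy copy; van der Waals
    radii come from the element table in `_tables`.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    ch = model.find_chain(chain)
    if ch is None:
        raise ValueError(f"chain {chain!r} not found in {path}")

    names, resnums, resnames, chains, elements, coords, radii = [], [], [], [], [], [], []
    for res in ch:
        # resolve altlocs: keep highest occupancy per atom name
        best: dict[str, gemmi.Atom] = {}
        for atom in res:
            if atom.element.is_hydrogen:
                continue
            prev = best.get(atom.name)
            if prev is None or atom.occ > prev.occ:
                best[atom.name] = atom
        for name, atom in best.items():
            names.append(name)
            resnums.append(res.seqid.num)
            resnames.append(res.name)
            chains.append(chain)
            el = atom.element.name.upper()
            elements.append(el)
            coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
            radii.append(vdw_radius(el))
    if not coords:
        raise ValueError(f"no heavy atoms for chain {chain!r} in {path}")
    return StructureModel(
        atom_names=np.array(names),
        residue_numbers=np.array(resnums, dtype=int),
        residue_names=np.array(resnames),
        chain_ids=np.array(chains),
        elements=np.array(elements),
        coords=np.asarray(coords, dtype=float),
        radii=np.asarray(radii, dtype=float),
    )


# ---------------------------------------------------------------------------
# titration alignment

@dataclass
class Trajectory:
    """Shift trajectory of one residue across titration points.

    Missing observations (peaks broadened out at some point) stay NaN: gaps are
    recorded, never interpolated.
    """

    residue_number: int
    ratios: np.ndarray
    shift_H: np.ndarray
    shift_N: np.ndarray

    @property
    def n_observed(self) -> int:
        return int(np.sum(np.isfinite(self.shift_H)))

    @property
    def observed_mask(self) -> np.ndarray:
        return np.isfinite(self.shift_H)


def match_titration_peaks(
    series: TitrationSeries,
    weight_N: float = 0.2,
    jump_threshold: float = 0.15,
) -> dict[int, Trajectory]:
    """Align assigned peaks across titration points into per-residue trajectories.

    Matching is by identical assignment (residue number).  A weighted shift
    step between consecutive observed points above ``jump_threshold`` (ppm)
    triggers a warning flagging a likely mis-assignment; the trajectory is
    kept unchanged.
    """
    maps = [p.peak_map() for p in series.points]
    ratios = np.array(series.ratios, dtype=float)
    free_residues = sorted(maps[0].keys())
    out: dict[int, Trajectory] = {}
    for res in free_residues:
        h = np.full(len(maps), np.nan)
        n = np.full(len(maps), np.nan)
        for i, m in enumerate(maps):
            if res in m:
                h[i] = m[res].shift_H
                n[i] = m[res].shift_N
        traj = Trajectory(res, ratios, h, n)
        obs = np.flatnonzero(traj.observed_mask)
        for a, b in zip(obs, obs[1:]):
            step = np.hypot(h[b] - h[a], weight_N * (n[b] - n[a]))
            if step > jump_threshold:
                warnings.warn(
                    f"residue {res}: weighted shift step {step:.3f} ppm between "
                    f"ratios {ratios[a]:g} and {ratios[b]:g} exceeds jump threshold "
                    f"{jump_threshold:g}; check assignment",
                    stacklevel=2,
                )
        out[res] = traj
    return out
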