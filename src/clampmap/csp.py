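"""Chemical-shift perturbation (CSP) profiles and perturbed-residue selection.

The combined amide perturbation is

    dd_av = sqrt(dd_H^2 + (w_N * dd_N)^2)

with dd_H and dd_N the 1H and 15N shift differences between the free and bound
states of the same amide and w_N the nitrogen scaling factor (default 1/5,
compensating the wider 15N shift dispersion; 0.14 and 0.10 are common
alternatives and can be passed instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

from .io import AssignedPeak, Trajectory

__all__ = [
    "CSPRecord",
    "CSPProfile",
    "compute_csp",
    "build_csp_profile",
    "classify_perturbed",
    "profile_to_frame",
    "write_csp_csv",
    "write_bfactor_pdb",
]

DEFAULT_WEIGHT_N = 0.2


@dataclass(frozen=True)
class CSPRecord:
    residue_number: int
    delta_H: float
    delta_N: float
    delta_av: float

    def __post_init__(self) -> None:
        if self.delta_av < 0:
            raise ValueError("delta_av must be >= 0")


@dataclass
class CSPProfile:
    """Per-residue perturbations between two titration points.

    ``unobserved`` lists residues present at one point but broadened out or
    unassigned at the other; they carry no record.
    """

    records: list[CSPRecord]
    reference_ratio: float
    observation_ratio: float
    unobserved: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: r.residue_number)
        seen = [r.residue_number for r in self.records]
        if len(set(seen)) != len(seen):
            raise ValueError("duplicate residue in CSP profile")

    def as_dict(self) -> dict[int, float]:
        return {r.residue_number: r.delta_av for r in self.records}


def compute_csp(
    free: AssignedPeak, bound: AssignedPeak, weight_N: float = DEFAULT_WEIGHT_N
) -> CSPRecord:
    """Combined shift perturbation of one amide between two states."""
    if free.residue_number != bound.residue_number:
        raise ValueError(
            f"residue mismatch: {free.residue_number} vs {bound.residue_number}"
        )
    d_h = free.shift_H - bound.shift_H
    d_n = free.shift_N - bound.shift_N
    d_av = float(np.hypot(d_h, weight_N * d_n))
    return CSPRecord(free.residue_number, d_h, d_n, d_av)


def build_csp_profile(
    trajectories: dict[int, Trajectory],
    observation_ratio: float,
    reference_ratio: float = 0.0,
    weight_N: float = DEFAULT_WEIGHT_N,
) -> CSPProfile:
    """CSP profile between two molar ratios of a matched titration series."""
    records: list[CSPRecord] = []
    unobserved: list[int] = []
    i_ref = i_obs = None
    for res, traj in trajectories.items():
        if i_ref is None:
            i_ref = _ratio_index(traj.ratios, reference_ratio)
            i_obs = _ratio_index(traj.ratios, observation_ratio)
        ok_ref = np.isfinite(traj.shift_H[i_ref])
        ok_obs = np.isfinite(traj.shift_H[i_obs])
        if ok_ref and ok_obs:
            d_h = traj.shift_H[i_ref] - traj.shift_H[i_obs]
            d_n = traj.shift_N[i_ref] - traj.shift_N[i_obs]
            records.append(
                CSPRecord(res, float(d_h), float(d_n), float(np.hypot(d_h, weight_N * d_n)))
            )
        else:
            unobserved.append(res)
    if i_ref is None:
        raise ValueError("no trajectories given")
    return CSPProfile(records, reference_ratio, observation_ratio, sorted(unobserved))


def _ratio_index(ratios: np.ndarray, ratio: float) -> int:
    idx = np.flatnonzero(np.isclose(ratios, ratio))
    if idx.size == 0:
        raise ValueError(f"molar ratio {ratio} not present in series (have {list(ratios)})")
    return int(idx[0])


def classify_perturbed(profile: CSPProfile, threshold: float = 0.10) -> set[int]:
    """Residues with delta_av strictly greater than ``threshold`` (ppm)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return {r.residue_number for r in profile.records if r.delta_av > threshold}


def profile_to_frame(profile: CSPProfile, threshold: float = 0.10) -> pd.DataFrame:
    perturbed = classify_perturbed(profile, threshold)
    rows = [
        {
            "residue": r.residue_number,
            "delta_H": r.delta_H,
            "delta_N": r.delta_N,
            "delta_av": r.delta_av,
            "flag": "perturbed" if r.residue_number in perturbed else "",
        }
        for r in profile.records
    ]
    rows += [
        {"residue": res, "delta_H": np.nan, "delta_N": np.nan,
         "delta_av": np.nan, "flag": "broadened/unobserved"}
        for res in profile.unobserved
    ]
    return pd.DataFrame(rows).sort_values("residue").reset_index(drop=True)


def write_csp_csv(profile: CSPProfile, path, threshold: float = 0.10) -> None:
    profile_to_frame(profile, threshold).to_csv(path, index=False)


def write_bfactor_pdb(structure_path, profile: CSPProfile, out_path,
                      chain: str | None = None, offset: int = 0) -> None:
    """Copy a PDB with delta_av written into the B-factor column.

    ``offset`` maps peak-list numbering to structure numbering
    (structure_number = peaklist_number + offset).  Residues without a CSP
    record get B = 0.
    """
    values = {r.residue_number + offset: r.delta_av for r in profile.records}
    st = gemmi.read_structure(str(structure_path))
    for model in st:
        for ch in model:
            if chain is not None and ch.name != chain:
                continue
            for res in ch:
                b = values.get(res.seqid.num, 0.0)
                for atom in res:
                    atom.b_iso = b
    st.write_pdb(str(out_path))
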