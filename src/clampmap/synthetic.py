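"""Synthetic data generators emulating the study's data-generating conditions.

Every generator is a pure function of a `GeneratorSpec` (which carries the
seed), so outputs are byte-identical across runs.  Defaults encode the
conditions the analyses assume:

* titrations: 1:1 fast exchange at K_d = 3.27 uM with the labelled protein at
  10 uM and twelve molar ratios from 0 to 8; only the C-terminal reporter
  residues (404-407) shift, the rest are negative controls;
* hetNOE: a rigid core with a flexible C-terminal tail whose five-residue
  window (403-407) averages exactly -0.71 free and 0.48 bound;
* PRE: r^-6 broadening from a spin label on a structure, in the reduced
  parametrization Gamma2(r) = Gamma2_ref (r_ref/r)^6 with
  ratio = R2/(R2+Gamma2) * exp(-Gamma2 t);
* ITC: the one-site perfusion model under the standard protocol (1 mM titrant,
  20 x 2 uL injections into 50 uM, 298 K) plus Gaussian heat noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import bound_fraction
from .dynamics import label_site_coordinate
from .io import AssignedPeak, StructureModel, TitrationPoint, TitrationSeries
from .itc import ITCProtocol, Thermogram, ThermoParams, derive_thermo, paper_protocol, simulate_injection_heats

__all__ = [
    "PREParams",
    "GeneratorSpec",
    "gen_titration_dataset",
    "gen_hetnoe_dataset",
    "gen_pre_dataset",
    "gen_itc_thermogram",
    "gen_toy_structure",
    "write_toy_pdb",
    "pre_ratio_model",
    "default_noe_profile",
]

_DEFAULT_RATIOS = (0.0, 0.2, 0.5, 0.7, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0)
_DEFAULT_DELTA_MAX = {404: 0.10, 405: 0.15, 406: 0.20, 407: 0.25}
_TAIL_TYPES = {403: "D", 404: "M", 405: "S", 406: "L", 407: "D"}


@dataclass
class PREParams:
    """Reduced PRE forward-model parameters.

    The default ``gamma2_ref`` is calibrated so the noise-free intensity
    ratio at 20 A equals the default broadening threshold (0.7): data
    generated with these defaults are internally consistent with the
    "broadened means within 20 A of the label" interpretation.
    """

    R2: float = 15.0            # intrinsic transverse rate, 1/s
    gamma2_ref: float = 30.0    # PRE rate at the reference distance, 1/s
    r_ref: float = 15.0         # reference distance, A
    t_evol: float = 0.010       # effective transverse evolution time, s


@dataclass
class GeneratorSpec:
    """Ground-truth parameters and noise levels for all generators."""

    seed: int = 0
    # titration
    K_d_true: float = 3.27                      # uM
    delta_max_map: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_DELTA_MAX))
    P_tot: float = 10.0                         # uM labelled protein
    ratios: tuple[float, ...] = _DEFAULT_RATIOS
    noise_csp: float = 0.004                    # ppm (1H-equivalent, per axis)
    control_residues: tuple[int, ...] = tuple(range(382, 404))
    weight_N: float = 0.2
    # hetNOE
    noise_noe: float = 0.02                     # fractional
    # PRE
    label_site: int = 1
    pre_params: PREParams = field(default_factory=PREParams)
    noise_pre: float = 0.02                     # fractional
    # ITC
    itc_thermo: ThermoParams = field(
        default_factory=lambda: derive_thermo(K_d=16.1, dH=-3.37))
    itc_protocol: ITCProtocol = field(default_factory=paper_protocol)
    noise_q: float = 0.05                       # ucal

    def __post_init__(self) -> None:
        if min(self.noise_csp, self.noise_noe, self.noise_pre, self.noise_q) < 0:
            raise ValueError("noise levels must be >= 0")
        if not self.delta_max_map:
            raise ValueError("delta_max_map must not be empty")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


# ---------------------------------------------------------------------------
# titrations

def gen_titration_dataset(spec: GeneratorSpec) -> TitrationSeries:
    """Fast-exchange titration series with per-residue linear trajectories.

    Each shifting residue moves along a fixed direction in the (1H, 15N)
    plane, by delta_max times the bound fraction at that ratio; Gaussian noise
    of sd ``noise_csp`` ppm is added on the 1H axis and ``noise_csp/weight_N``
    on the 15N axis so both axes contribute equally to the combined CSP noise.
    """
    rng = spec.rng(1)
    residues = sorted(set(spec.control_residues) | set(spec.delta_max_map))
    free_h = {r: rng.uniform(7.5, 9.3) for r in residues}
    free_n = {r: rng.uniform(108.0, 128.0) for r in residues}
    phi = {r: rng.uniform(0.0, 2.0 * np.pi) for r in residues}
    types = {r: _TAIL_TYPES.get(r, "ACDEFGHIKLMNPQRSTVWY"[rng.integers(0, 20)])
             for r in residues}
    points = []
    for ratio in spec.ratios:
        L = ratio * spec.P_tot
        f = bound_fraction(spec.P_tot, L, spec.K_d_true)
        peaks = []
        for r in residues:
            dmax = spec.delta_max_map.get(r, 0.0)
            dh = dmax * np.cos(phi[r]) * f
            dn = dmax * np.sin(phi[r]) / spec.weight_N * f
            h = free_h[r] - dh + rng.normal(0.0, spec.noise_csp)
            n = free_n[r] - dn + rng.normal(0.0, spec.noise_csp / spec.weight_N)
            peaks.append(AssignedPeak(r, types[r], float(h), float(n),
                                      intensity=float(rng.uniform(3e4, 6e4))))
        points.append(TitrationPoint(ratio, spec.P_tot, L, peaks))
    return TitrationSeries(points)


# ---------------------------------------------------------------------------
# hetNOE

_FREE_TAIL = {403: -0.55, 404: -0.65, 405: -0.71, 406: -0.77, 407: -0.87}
_BOUND_TAIL = {403: 0.30, 404: 0.40, 405: 0.48, 406: 0.56, 407: 0.66}


def default_noe_profile(state: str, residues=tuple(range(382, 408))) -> dict[int, float]:
    """Ground-truth NOE profile: structured core, flexible C-terminal tail.

    Tail values for residues 403-407 are constructed so their mean is exactly
    -0.71 in the free state and 0.48 bound.
    """
    if state == "free":
        ramp = {400: 0.40, 401: 0.10, 402: -0.20}
        tail, core = _FREE_TAIL, 0.75
    elif state == "bound":
        ramp = {400: 0.68, 401: 0.62, 402: 0.55}
        tail, core = _BOUND_TAIL, 0.78
    else:
        raise ValueError("state must be 'free' or 'bound'")
    out = {}
    for r in residues:
        out[r] = tail.get(r, ramp.get(r, core))
    return out


def gen_hetnoe_dataset(spec: GeneratorSpec, state: str = "free",
                       noe_profile: dict[int, float] | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Saturated and reference intensity tables for a NOE ground truth."""
    profile = noe_profile if noe_profile is not None else default_noe_profile(state)
    rng = spec.rng(2 if state == "free" else 3)
    rows_sat, rows_ref = [], []
    for res in sorted(profile):
        i_ref = rng.uniform(3e4, 6e4)
        i_sat = profile[res] * i_ref * (1.0 + rng.normal(0.0, spec.noise_noe))
        rows_ref.append({"residue": res, "intensity": i_ref})
        rows_sat.append({"residue": res, "intensity": i_sat})
    return pd.DataFrame(rows_sat), pd.DataFrame(rows_ref)


# ---------------------------------------------------------------------------
# PRE

def pre_ratio_model(r: float, params: PREParams) -> float:
    """Noise-free intensity ratio at distance ``r`` (A) from the label."""
    if r <= 0:
        raise ValueError("distance must be > 0")
    gamma2 = params.gamma2_ref * (params.r_ref / r) ** 6
    return params.R2 / (params.R2 + gamma2) * float(np.exp(-gamma2 * params.t_evol))


def gen_pre_dataset(spec: GeneratorSpec, structure: StructureModel
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paramagnetic and diamagnetic intensity tables from a structure + label.

    The true ratio for each residue follows `pre_ratio_model` at the
    amide-N-to-label distance; the label sits on `spec.label_site`.
    """
    label_xyz = label_site_coordinate(structure, spec.label_site)
    rng = spec.rng(4)
    rows_para, rows_dia = [], []
    for res in structure.residue_numbers_unique():
        res = int(res)
        try:
            n_xyz = structure.atom_coord(res, "N")
        except KeyError:
            continue
        r = float(np.linalg.norm(n_xyz - label_xyz))
        ratio = pre_ratio_model(r, spec.pre_params)
        i_dia = rng.uniform(3e4, 6e4)
        i_para = max(0.0, ratio * i_dia * (1.0 + rng.normal(0.0, spec.noise_pre)))
        rows_dia.append({"residue": res, "intensity": i_dia})
        rows_para.append({"residue": res, "intensity": i_para})
    return pd.DataFrame(rows_para), pd.DataFrame(rows_dia)


# ---------------------------------------------------------------------------
# ITC

def gen_itc_thermogram(spec: GeneratorSpec, dilution_offset: float = 0.0) -> Thermogram:
    """One-site thermogram under the generator's protocol plus Gaussian heat noise."""
    clean = simulate_injection_heats(spec.itc_thermo, spec.itc_protocol, dilution_offset)
    rng = spec.rng(5)
    noisy = [q + rng.normal(0.0, spec.noise_q) for q in clean.injection_heats]
    return Thermogram(noisy, spec.itc_protocol)


# ---------------------------------------------------------------------------
# toy structures

_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "CA-CB": 1.530}
_ANGLE = {"N-CA-C": 111.0, "CA-C-N": 116.6, "C-N-CA": 121.7,
          "CA-C-O": 120.5, "N-CA-CB": 110.5}
_TORSIONS = {"helix": (-57.0, -47.0), "extended": (-139.0, 135.0)}


def _nerf(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d from internal coordinates relative to frame (a, b, c)."""
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = bond * np.array([-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def gen_toy_structure(n_residues: int, geometry: str = "helix",
                      chain_id: str = "A") -> StructureModel:
    """Ideal poly-alanine backbone (N, CA, C, O, CB) with standard geometry.

    ``helix`` uses phi/psi = -57/-47 (1.5 A rise per residue); ``extended``
    uses beta-strand torsions.  Deterministic: no randomness involved.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if geometry not in _TORSIONS:
        raise ValueError(f"geometry must be one of {sorted(_TORSIONS)}")
    phi, psi = _TORSIONS[geometry]
    omega = 180.0

    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_BOND["N-CA"], 0.0, 0.0])]
    ang = np.deg2rad(_ANGLE["N-CA-C"])
    C = [CA[0] + _BOND["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    for i in range(1, n_residues):
        N.append(_nerf(N[-1], CA[-1], C[-1], _BOND["C-N"], _ANGLE["CA-C-N"], psi))
        CA.append(_nerf(CA[-1], C[-1], N[-1], _BOND["N-CA"], _ANGLE["C-N-CA"], omega))
        C.append(_nerf(C[-1], N[-1], CA[-1], _BOND["CA-C"], _ANGLE["N-CA-C"], phi))
    O, CB = [], []
    for i in range(n_residues):
        O.append(_nerf(N[i], CA[i], C[i], _BOND["C-O"], _ANGLE["CA-C-O"], psi + 180.0))
        CB.append(_nerf(C[i], N[i], CA[i], _BOND["CA-CB"], _ANGLE["N-CA-CB"], 122.6))

    names, resnums, coords = [], [], []
    for i in range(n_residues):
        for nm, xyz in (("N", N[i]), ("CA", CA[i]), ("C", C[i]), ("O", O[i]), ("CB", CB[i])):
            names.append(nm)
            resnums.append(i + 1)
            coords.append(xyz)
    n_atoms = len(names)
    elements = np.array([nm[0] for nm in names])
    from ._tables import vdw_radius
    return StructureModel(
        atom_names=np.array(names),
        residue_numbers=np.array(resnums, dtype=int),
        residue_names=np.array(["ALA"] * n_atoms),
        chain_ids=np.array([chain_id] * n_atoms),
        elements=elements,
        coords=np.round(np.asarray(coords, dtype=float), 3),
        radii=np.array([vdw_radius(e) for e in elements]),
    )


def write_toy_pdb(structure: StructureModel, path) -> None:
    """Write a StructureModel as a minimal, standards-conforming PDB file."""
    with open(path, "w") as fh:
        for i in range(len(structure)):
            name = structure.atom_names[i]
            namef = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = structure.coords[i]
            fh.write(
                f"ATOM  {i + 1:5d} {namef}{'':1s}{structure.residue_names[i]:>3s} "
                f"{structure.chain_ids[i]:1s}{structure.residue_numbers[i]:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                f"{structure.elements[i]:>2s}\n"
            )
        fh.write("END\n")
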