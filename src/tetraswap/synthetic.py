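"""Seeded generators emulating every input the analysis pipeline consumes.

Each generator carries known ground truth so that recovery tests can compare
fitted values against what generated the data.  The default ground truth
mirrors a light-chain monomer⇌tetramer system with ΔC°p = 0.78 kcal/mol/K,
T_h = 1 °C and T_s = 29 °C, SEC peaks at 13.1 mL (tetramer) and 16.4 mL
(monomer), a 300 µM stock diluted 50-fold for relaxation experiments, and
relaxation times spanning ~13.5 h at 4 °C to ~0.3 h at 45 °C (dissociation
rate constants are calibrated against those observables through the
near-equilibrium linearization and interpolated log-linearly in 1/T).

A single root seed derives an independent stream per artifact (CRC-32 of the
artifact name is mixed into the bit generator's seed sequence), so adding one
generator never perturbs the others.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .equilibrium import celsius_to_kelvin, solve_speciation
from .kinetics import RateConstants, TimeCourse, dilution_jump, k_off_from_tau
from .sec import Chromatogram, GaussianPeak, simulate_chromatogram
from .structure import AtomRecord, Residue, StructureModel
from .thermo import ThermoParams, delta_g_model, k_from_delta_g

__all__ = [
    "GroundTruth",
    "ToyStructures",
    "generate_equilibrium_dataset",
    "generate_timecourses",
    "generate_chromatogram",
    "generate_toy_structures",
    "write_dataset",
]

DEFAULT_TEMPERATURES_C = (4.0, 10.0, 17.0, 25.0, 31.0, 38.0, 45.0)
DEFAULT_CONCENTRATIONS_UM = (3.0, 10.0, 30.0, 100.0, 300.0)

_CALIBRATION_CACHE: dict[tuple, float] = {}


def _calibrated_k_off(
    cache_key: tuple, tau_target: float, kd: float, c_stock: float, dilution: float
) -> float:
    """k_off such that the exponential fit of the simulated dilution jump has
    relaxation time ``tau_target``.  Deterministic; memoized per ground truth."""
    from scipy.optimize import brentq

    from .kinetics import fit_relaxation

    key = (cache_key, tau_target)
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    grid = np.linspace(0.0, 5.0 * tau_target, 25)

    def fitted_tau(log10_k: float) -> float:
        k_off = 10.0**log10_k
        rates = RateConstants(k_off=k_off, k_on=k_off / kd)
        return fit_relaxation(dilution_jump(rates, c_stock, dilution, grid)).tau

    # start from the linearized inversion and bracket around it
    k_lin = k_off_from_tau(tau_target, kd, c_stock / dilution).k_off
    lo, hi = np.log10(k_lin) - 2.0, np.log10(k_lin) + 3.0
    log_k = brentq(lambda x: np.log(fitted_tau(x)) - np.log(tau_target), lo, hi,
                   xtol=1e-10, maxiter=100)
    _CALIBRATION_CACHE[key] = float(10.0**log_k)
    return _CALIBRATION_CACHE[key]


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters for every synthetic artifact."""

    thermo: ThermoParams = ThermoParams(delta_cp=0.78, t_h=274.15, t_s=302.15)
    # relaxation-time calibration points for the rate model (h at K)
    tau_cold_h: float = 13.5
    t_cold: float = celsius_to_kelvin(4.0)
    tau_hot_h: float = 0.3
    t_hot: float = celsius_to_kelvin(45.0)
    c_stock: float = 300e-6  # M, equilibrated stock before dilution
    dilution_factor: float = 50.0
    # SEC peak geometry (mL): tetramer elutes first
    center_tet: float = 13.1
    center_mono: float = 16.4
    sigma_tet: float = 0.35
    sigma_mono: float = 0.35
    # noise levels
    ratio_noise_sd: float = 0.03  # relative, on each SEC peak area
    chromatogram_noise_sd: float = 0.002  # AU
    timecourse_noise_sd: float = 0.01  # absolute, on f_tet
    seed: int = 7

    def rng(self, artifact: str) -> np.random.Generator:
        """Independent, reproducible stream for one named artifact."""
        return np.random.default_rng(
            [self.seed & 0x7FFFFFFF, zlib.crc32(artifact.encode("utf-8"))]
        )

    def kd(self, temperature: float) -> float:
        """Ground-truth K_D(T) implied by the thermodynamic parameters."""
        return k_from_delta_g(
            float(delta_g_model(self.thermo, temperature)), temperature
        ).value

    def tau_anchor(self, temperature: float) -> float:
        """Expected exponential-fit relaxation time, log-linear in 1/T between anchors."""
        slope = (np.log(self.tau_hot_h) - np.log(self.tau_cold_h)) / (
            1.0 / self.t_hot - 1.0 / self.t_cold
        )
        return float(
            np.exp(np.log(self.tau_cold_h) + slope * (1.0 / temperature - 1.0 / self.t_cold))
        )

    def rates(self, temperature: float) -> RateConstants:
        """Mass-action rates at T, calibrated to the relaxation-time anchors.

        The anchor relaxation times are exponential fits of full dilution-jump
        experiments, which are far outside linear response; k_off is therefore
        calibrated at the two anchor temperatures by root-finding so that an
        exponential fit of the *simulated* 50-fold jump reproduces the anchor
        tau, then interpolated log-linearly in 1/T (Arrhenius-like).  k_on
        follows from detailed balance, k_on = k_off / K(T).
        """
        key = (
            self.thermo.delta_cp, self.thermo.t_h, self.thermo.t_s,
            self.tau_cold_h, self.t_cold, self.tau_hot_h, self.t_hot,
            self.c_stock, self.dilution_factor,
        )
        k_cold = _calibrated_k_off(
            key, self.tau_cold_h, self.kd(self.t_cold), self.c_stock, self.dilution_factor
        )
        k_hot = _calibrated_k_off(
            key, self.tau_hot_h, self.kd(self.t_hot), self.c_stock, self.dilution_factor
        )
        slope = (np.log(k_hot) - np.log(k_cold)) / (1.0 / self.t_hot - 1.0 / self.t_cold)
        log_k = np.log(k_cold) + slope * (1.0 / temperature - 1.0 / self.t_cold)
        k_off = float(np.exp(log_k))
        return RateConstants(k_off=k_off, k_on=k_off / self.kd(temperature))


def generate_equilibrium_dataset(
    truth: GroundTruth,
    temperatures: list[float] | None = None,
    concentrations: list[float] | None = None,
    ratio_noise_sd: float | None = None,
) -> pd.DataFrame:
    """Equilibrium speciation table (temperature_C, c_total_uM, f_mono, f_tet).

    For every (T, c): K_D from the ground-truth thermodynamic model, f_mono
    from the exact speciation solve, then measurement noise applied as
    independent Gaussian *relative* perturbations of the monomer and tetramer
    peak areas (each with standard deviation ``ratio_noise_sd``), from which
    the observed fraction is recomputed.  This mirrors how SEC fractions are
    actually measured — each fitted peak area carries a roughly constant
    relative error, so the uncertainty of the fraction vanishes toward 0
    and 1.  The default of 3% per area reproduces a dissociation-constant
    scatter of roughly ±14% across concentrations, matching the dispersion
    such SEC-derived K_D tables typically show.  The result is clipped to the
    open interval (0, 1).
    """
    temps = (
        [celsius_to_kelvin(t) for t in DEFAULT_TEMPERATURES_C]
        if temperatures is None
        else list(temperatures)
    )
    concs = (
        [c * 1e-6 for c in DEFAULT_CONCENTRATIONS_UM]
        if concentrations is None
        else list(concentrations)
    )
    noise = truth.ratio_noise_sd if ratio_noise_sd is None else ratio_noise_sd
    rng = truth.rng("equilibrium")
    rows = []
    for t_K in temps:
        k = truth.kd(t_K)
        for c in concs:
            f = solve_speciation(k, c).f_mono
            if noise > 0:
                eps_m, eps_t = rng.normal(0.0, noise, size=2)
                area_m = max(f * (1.0 + eps_m), 1e-9)
                area_t = max((1.0 - f) * (1.0 + eps_t), 1e-9)
                f = float(np.clip(area_m / (area_m + area_t), 1e-6, 1.0 - 1e-6))
            rows.append(
                {
                    "temperature_C": t_K - 273.15,
                    "c_total_uM": c * 1e6,
                    "f_mono": f,
                    "f_tet": 1.0 - f,
                }
            )
    return pd.DataFrame(rows)


def generate_timecourses(
    truth: GroundTruth,
    temperatures: list[float] | None = None,
    sampling: np.ndarray | None = None,
    noise_sd: float | None = None,
    dilution_factor: float | None = None,
) -> dict[float, TimeCourse]:
    """Post-dilution relaxation time courses keyed by temperature (K).

    The initial state is the equilibrium at the stock concentration; the
    trajectory is the mass-action ODE solution after instantaneous dilution,
    plus observation noise on the tetramer fraction.
    """
    temps = (
        [celsius_to_kelvin(t) for t in DEFAULT_TEMPERATURES_C]
        if temperatures is None
        else list(temperatures)
    )
    noise = truth.timecourse_noise_sd if noise_sd is None else noise_sd
    dilution = truth.dilution_factor if dilution_factor is None else dilution_factor
    out: dict[float, TimeCourse] = {}
    for t_K in temps:
        rates = truth.rates(t_K)
        grid = (
            sampling
            if sampling is not None
            else np.linspace(0.0, 5.0 * truth.tau_anchor(t_K), 25)
        )
        tc = dilution_jump(rates, truth.c_stock, dilution, grid)
        f = tc.f_tet
        if noise > 0:
            rng = truth.rng(f"timecourse-{t_K:.4f}")
            f = np.clip(f + rng.normal(0.0, noise, size=f.size), 0.0, 1.0)
        out[t_K] = TimeCourse(times=tc.times, f_tet=f)
    return out


def generate_chromatogram(
    truth: GroundTruth,
    f_mono: float,
    total_area: float = 1.0,
    noise_sd: float | None = None,
    artifact: str = "chromatogram",
    volume_grid: np.ndarray | None = None,
) -> tuple[Chromatogram, tuple[GaussianPeak, GaussianPeak]]:
    """SEC trace with tetramer/monomer Gaussian peaks at given mass fractions.

    Returns the trace and the generating peaks (tetramer first).
    """
    if not (0.0 <= f_mono <= 1.0):
        raise ValueError("f_mono must lie in [0, 1]")
    area_t = (1.0 - f_mono) * total_area
    area_m = f_mono * total_area
    sqrt2pi = np.sqrt(2.0 * np.pi)
    peaks = (
        GaussianPeak(truth.center_tet, truth.sigma_tet, area_t / (truth.sigma_tet * sqrt2pi)),
        GaussianPeak(truth.center_mono, truth.sigma_mono, area_m / (truth.sigma_mono * sqrt2pi)),
    )
    noise = truth.chromatogram_noise_sd if noise_sd is None else noise_sd
    seed = int(truth.rng(artifact).integers(0, 2**31 - 1))
    chrom = simulate_chromatogram(
        peaks, baseline=(0.0, 0.0), noise_sd=noise, seed=seed, volume_grid=volume_grid
    )
    return chrom, peaks


# ---------------------------------------------------------------------------
# toy structures

@dataclass(frozen=True)
class ToyStructures:
    """Coordinate fixtures with declared ground truth.

    ``beta_ladder``: two strands whose only cross-chain polar contacts are the
    declared N-O pairs.  ``unswapped``: two separated copies of a compact
    fold, each with its own C-terminal tail docked against its own core.
    ``swapped``: the same two folds with the C-terminal tails exchanged, so
    residues ``swap_range`` of each chain pack exclusively against the
    partner chain.
    """

    beta_ladder: StructureModel
    declared_bonds: tuple  # ((chain, res_id, atom), (chain, res_id, atom), distance)
    unswapped: StructureModel
    swapped: StructureModel
    swap_range: tuple[str, str]  # inclusive residue-id range of the swapped tail
    n_residues: int


def _atom(chain: str, res_name: str, seq: int, name: str, element: str, xyz) -> AtomRecord:
    return AtomRecord(
        chain_id=chain,
        res_name=res_name,
        res_seq=seq,
        icode="",
        atom_name=name,
        element=element,
        xyz=tuple(float(v) for v in xyz),
    )


def _beta_ladder(n_res: int = 5) -> tuple[StructureModel, tuple]:
    chains: dict[str, list[Residue]] = {"A": [], "B": []}
    bonds = []
    for i in range(n_res):
        x = 6.0 * i
        ra = Residue("A", "GLY", i + 1, "")
        ra.atoms = [
            _atom("A", "GLY", i + 1, "N", "N", (x, 0.0, 0.0)),
            _atom("A", "GLY", i + 1, "CA", "C", (x + 1.5, 0.0, 0.0)),
            _atom("A", "GLY", i + 1, "C", "C", (x + 3.0, 0.0, 0.0)),
            _atom("A", "GLY", i + 1, "O", "O", (x + 3.0, 1.2, 0.0)),
        ]
        rb = Residue("B", "GLY", i + 1, "")
        rb.atoms = [
            _atom("B", "GLY", i + 1, "N", "N", (x + 3.0, 4.1, 0.0)),
            _atom("B", "GLY", i + 1, "CA", "C", (x + 4.5, 4.1, 0.0)),
            _atom("B", "GLY", i + 1, "C", "C", (x + 6.0, 4.1, 0.0)),
            _atom("B", "GLY", i + 1, "O", "O", (x + 6.0, 5.3, 0.0)),
        ]
        chains["A"].append(ra)
        chains["B"].append(rb)
        # A residue i carbonyl O sits 2.9 A below B residue i amide N
        bonds.append((("A", str(i + 1), "O"), ("B", str(i + 1), "N"), 2.9))
    return StructureModel(chains), tuple(bonds)


def _fold_positions() -> tuple[list, list]:
    """A compact 24-residue core (3 rows x 4 cols x 2 layers, 4 Å grid) plus a
    6-residue C-terminal tail docked against the core face at y = -3."""
    core = []
    for k in range(24):
        col, row, layer = k % 4, (k // 4) % 3, k // 12
        core.append((4.0 * col, 4.0 * row, 4.0 * layer))
    tail = [
        (2.0, -3.0, 0.0),
        (6.0, -3.0, 0.0),
        (10.0, -3.0, 0.0),
        (10.0, -3.0, 4.0),
        (6.0, -3.0, 4.0),
        (2.0, -3.0, 4.0),
    ]
    return core, tail


def _dimer(swapped: bool) -> StructureModel:
    core, tail = _fold_positions()
    offset = np.array([40.0, 0.0, 0.0]) if swapped else np.array([60.0, 0.0, 0.0])
    chains: dict[str, list[Residue]] = {"A": [], "B": []}
    sites = {"A": np.zeros(3), "B": offset}
    for chain in ("A", "B"):
        own = sites[chain]
        partner = sites["B" if chain == "A" else "A"]
        for k, pos in enumerate(core):
            r = Residue(chain, "ALA", k + 1, "")
            r.atoms = [_atom(chain, "ALA", k + 1, "CA", "C", np.asarray(pos) + own)]
            chains[chain].append(r)
        tail_site = partner if swapped else own
        for m, pos in enumerate(tail):
            seq = 25 + m
            r = Residue(chain, "ALA", seq, "")
            r.atoms = [_atom(chain, "ALA", seq, "CA", "C", np.asarray(pos) + tail_site)]
            chains[chain].append(r)
    return StructureModel(chains)


def generate_toy_structures(truth: GroundTruth | None = None) -> ToyStructures:
    """Deterministic coordinate fixtures (no randomness is involved)."""
    ladder, bonds = _beta_ladder()
    return ToyStructures(
        beta_ladder=ladder,
        declared_bonds=bonds,
        unswapped=_dimer(swapped=False),
        swapped=_dimer(swapped=True),
        swap_range=("25", "30"),
        n_residues=30,
    )


def model_to_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel to a PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = "synthetic"
    gm = gemmi.Model("1")
    for cid, residues in model.chains.items():
        chain = gemmi.Chain(cid)
        for r in residues:
            res = gemmi.Residue()
            res.name = r.res_name
            res.seqid = gemmi.SeqId(r.res_seq, r.icode if r.icode else " ")
            for a in r.atoms:
                atom = gemmi.Atom()
                atom.name = a.atom_name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.xyz)
                atom.occ = a.occupancy
                atom.b_iso = a.b_factor
                res.add_atom(atom)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def write_dataset(truth: GroundTruth, outdir: str | Path) -> dict:
    """Write the full synthetic dataset in the formats the readers consume.

    Emits the equilibrium CSV, per-temperature time-course CSVs, a 300 µM
    chromatogram CSV, PDB files of the toy structures, and a JSON manifest
    recording the ground truth next to the data.  Returns the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    eq = generate_equilibrium_dataset(truth)
    eq.to_csv(outdir / "equilibrium.csv", index=False)

    tcs = generate_timecourses(truth)
    tc_files = {}
    for t_K, tc in tcs.items():
        t_C = t_K - 273.15
        name = f"timecourse_{t_C:g}C.csv"
        pd.DataFrame({"time_h": tc.times, "f_tet": tc.f_tet}).to_csv(
            outdir / name, index=False
        )
        tc_files[f"{t_C:g}"] = name

    f25 = solve_speciation(truth.kd(celsius_to_kelvin(25.0)), truth.c_stock).f_mono
    chrom, _peaks = generate_chromatogram(truth, f25, artifact="chromatogram-300uM")
    pd.DataFrame({"volume_mL": chrom.volumes, "a280": chrom.absorbance}).to_csv(
        outdir / "chromatogram_300uM.csv", index=False
    )

    toys = generate_toy_structures(truth)
    model_to_pdb(toys.beta_ladder, outdir / "beta_ladder.pdb")
    model_to_pdb(toys.unswapped, outdir / "unswapped_dimer.pdb")
    model_to_pdb(toys.swapped, outdir / "swapped_dimer.pdb")

    manifest = {
        "seed": truth.seed,
        "thermo": {
            "delta_cp_kcal_mol_K": truth.thermo.delta_cp,
            "t_h_K": truth.thermo.t_h,
            "t_s_K": truth.thermo.t_s,
        },
        "tau_anchors_h": {"cold": truth.tau_cold_h, "hot": truth.tau_hot_h},
        "c_stock_M": truth.c_stock,
        "dilution_factor": truth.dilution_factor,
        "peaks_mL": {"tetramer": truth.center_tet, "monomer": truth.center_mono},
        "noise": {
            "ratio_sd": truth.ratio_noise_sd,
            "chromatogram_sd": truth.chromatogram_noise_sd,
            "timecourse_sd": truth.timecourse_noise_sd,
        },
        "files": {
            "equilibrium": "equilibrium.csv",
            "timecourses": tc_files,
            "chromatogram_300uM": "chromatogram_300uM.csv",
            "structures": {
                "beta_ladder": "beta_ladder.pdb",
                "unswapped_dimer": "unswapped_dimer.pdb",
                "swapped_dimer": "swapped_dimer.pdb",
            },
        },
        "toy_structure_truth": {
            "declared_bonds": [list(map(list, b[:2])) + [b[2]] for b in toys.declared_bonds],
            "swap_range": list(toys.swap_range),
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
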