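"""Synthetic-data generators with known ground truth for every pipeline stage.

Three forward models invert the analyses in this package:

* titrations: signal = APC_min + APC_sat*c/(c+K_D) + APC_ns*c + Gaussian noise;
* melts: two-state van't Hoff unfolding with zero heat-capacity change,
  f(T) = 1 / (1 + exp(-dH (1 - T/Tm) / (R T))) in Kelvin, mixed between two
  sloped linear baselines, plus Gaussian noise -- the simplest forward model
  whose inverse is the baseline/fraction-folded/transition-regression analysis;
* trajectories: i.i.d. frames in which each probe particle is either placed
  in a thin shell around a designated "hydrophobic" surface atom (with a
  probability calibrated so designated atoms see ``enrichment`` times the
  background probe density) or uniformly in the box away from the protein.

``gen_pseries_bundle`` assembles a full synthetic study -- a wild-type VH
lineage with evolved variants and single-reversion constructs, titration and
melt CSVs, and a truth sidecar recording the generating parameters and the
trade-off classes they imply -- so the whole analysis can be exercised and
scored end to end without any instrument data.

All randomness descends from one integer seed through per-(variant,
replicate) ``numpy`` seed sequences, so adding replicates never perturbs
earlier ones and identical inputs give identical output bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binding import TitrationDataset, binding_model
from .kabat import VhVariant, apply_mutations, lineage_from_dict, lineage_to_dict, parse_mutation
from .melt import MeltCurve
from .structmap import Trajectory
from .tradeoff import NOT_COMPUTABLE

__all__ = [
    "TitrationTruth",
    "MeltTruth",
    "TrajectoryTruth",
    "PseriesBundle",
    "gen_titration",
    "gen_melt",
    "gen_trajectory",
    "gen_pseries_bundle",
    "make_toy_protein",
    "synthetic_wildtype",
    "build_pseries_lineage",
    "AFFINITY_TRUTH_PER_M",
    "TM_TRUTH_C",
]

R_KJ_PER_MOL_K = 8.314462618e-3


def _rng(seed: int, *stream: int) -> np.random.Generator:
    """Counter-style stream split: one root seed, a spawn key per stream."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=stream))


# ---------------------------------------------------------------------------
# Titrations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TitrationTruth:
    """Generating parameters for replicate titrations of one variant."""

    variant: str
    apc_min: float = 100.0
    apc_sat: float = 2000.0
    apc_ns: float = 1e7        # a.u. per molar
    kd: float = 5e-8           # molar
    concentrations: tuple[float, ...] | None = None
    noise_sd: float = 20.0     # a.u.
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.noise_sd < 0:
            raise ValueError("kd must be > 0 and noise_sd >= 0")

    def ladder(self) -> np.ndarray:
        """Default design: 10 half-log steps bracketing K_D."""
        if self.concentrations is not None:
            return np.asarray(self.concentrations, float)
        return self.kd * 10.0 ** np.arange(-2.25, 2.5, 0.5)


def gen_titration(truth: TitrationTruth, stream: int = 0) -> list[TitrationDataset]:
    conc = truth.ladder()
    clean = binding_model(conc, truth.apc_min, truth.apc_sat, truth.apc_ns, truth.kd)
    out = []
    for rep in range(truth.n_replicates):
        rng = _rng(truth.seed, 0, stream, rep)
        signal = clean + rng.normal(0.0, truth.noise_sd, size=conc.shape)
        out.append(
            TitrationDataset(
                variant=truth.variant,
                replicate_id=rep,
                points=tuple(zip(conc, signal)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Melts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeltTruth:
    """Generating parameters for replicate two-state melts of one variant."""

    variant: str
    tm: float = 66.0                   # degC
    dh_vant_hoff: float = 400.0        # kJ/mol
    folded_baseline: tuple[float, float] = (-0.01, -2.0)    # slope, intercept
    unfolded_baseline: tuple[float, float] = (-0.002, -14.0)
    temp_grid: tuple[float, float, float] = (25.0, 95.0, 0.5)  # start, stop, step
    noise_sd: float = 0.3              # mdeg
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dh_vant_hoff <= 0:
            raise ValueError("van't Hoff dH must be positive")
        lo, hi, _ = self.temp_grid
        if not (lo < self.tm < hi):
            raise ValueError("tm must lie inside the temperature grid")

    def temperatures(self) -> np.ndarray:
        lo, hi, step = self.temp_grid
        return np.arange(lo, hi + step / 2, step)

    def fraction_folded(self, t_c: np.ndarray) -> np.ndarray:
        t_k = np.asarray(t_c, float) + 273.15
        tm_k = self.tm + 273.15
        dg = self.dh_vant_hoff * (1.0 - t_k / tm_k)
        return 1.0 / (1.0 + np.exp(-dg / (R_KJ_PER_MOL_K * t_k)))

    def clean_signal(self, t_c: np.ndarray) -> np.ndarray:
        f = self.fraction_folded(t_c)
        theta_f = self.folded_baseline[0] * t_c + self.folded_baseline[1]
        theta_u = self.unfolded_baseline[0] * t_c + self.unfolded_baseline[1]
        return f * theta_f + (1.0 - f) * theta_u


def gen_melt(truth: MeltTruth, stream: int = 0) -> list[MeltCurve]:
    """Replicate first-heating scans; noiseless signal at T = Tm is midway
    between the baselines because f(Tm) = 0.5 exactly."""
    t = truth.temperatures()
    clean = truth.clean_signal(t)
    out = []
    for rep in range(truth.n_replicates):
        rng = _rng(truth.seed, 1, stream, rep)
        signal = clean + rng.normal(0.0, truth.noise_sd, size=t.shape)
        out.append(MeltCurve(variant=truth.variant, scan=1, points=tuple(zip(t, signal))))
    return out


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectoryTruth:
    """Generator settings for a probe-enriched i.i.d.-frame trajectory.

    ``enrichment`` is the target ratio of probe density near designated
    atoms to the background density; 1 means uniform.  Defaults mirror the
    probe-simulation setup this generator emulates (80 methane-like
    particles around a solvated domain), but frames are independent samples,
    not dynamics.
    """

    protein_coords: np.ndarray          # (n_atoms, 3) nm
    designated: tuple[int, ...] = ()
    n_probes: int = 80
    enrichment: float = 1.0
    n_frames: int = 200
    box: float = 6.0                    # cubic box edge [nm]
    exclusion: float = 0.35             # min probe-protein distance [nm]
    shell_outer: float = 0.5            # designated-atom shell outer radius [nm]
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "protein_coords", np.asarray(self.protein_coords, float)
        )
        if self.enrichment < 1:
            raise ValueError("enrichment must be >= 1")
        if self.n_probes < 1:
            raise ValueError("need at least one probe")
        if self.enrichment > 1 and not self.designated:
            raise ValueError("enrichment > 1 requires a designated atom set")


def make_toy_protein(n_atoms: int = 60, radius: float = 1.0) -> np.ndarray:
    """Heavy-atom shell on a Fibonacci sphere [nm]; all atoms are equivalent
    by symmetry, which makes uniformity checks of probe counts meaningful."""
    i = np.arange(n_atoms)
    golden = (1 + 5**0.5) / 2
    z = 1 - 2 * (i + 0.5) / n_atoms
    theta = 2 * np.pi * i / golden
    r = np.sqrt(1 - z**2)
    return radius * np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def gen_trajectory(truth: TrajectoryTruth) -> Trajectory:
    """Place probes frame by frame: enriched-shell placement with calibrated
    probability, otherwise uniform-in-box with protein exclusion."""
    rng = _rng(truth.seed, 2)
    box = np.full(3, float(truth.box))
    protein = truth.protein_coords - truth.protein_coords.mean(axis=0) + box / 2
    n_atoms = len(protein)
    v_box = float(np.prod(box))
    v_excluded = n_atoms * (4 / 3) * np.pi * truth.exclusion**3
    v_free = max(v_box - v_excluded, 0.1 * v_box)
    v_shell = (4 / 3) * np.pi * (truth.shell_outer**3 - truth.exclusion**3)
    if truth.designated:
        a = len(truth.designated) * v_shell / v_free
        excess = (truth.enrichment - 1.0) * a
        q_shell = excess / (1.0 + excess)
    else:
        q_shell = 0.0

    frames = np.empty((truth.n_frames, n_atoms + truth.n_probes, 3))
    for fi in range(truth.n_frames):
        frames[fi, :n_atoms] = protein
        for pi in range(truth.n_probes):
            if q_shell > 0 and rng.random() < q_shell:
                center = protein[truth.designated[rng.integers(len(truth.designated))]]
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                r3 = rng.uniform(truth.exclusion**3, truth.shell_outer**3)
                pos = center + direction * r3 ** (1 / 3)
                pos %= box
            else:
                for _ in range(10_000):
                    pos = rng.uniform(0.0, box)
                    delta = protein - pos
                    delta -= box * np.round(delta / box)
                    if np.min(np.sum(delta**2, axis=1)) >= truth.exclusion**2:
                        break
                else:
                    raise ValueError("box too small to place probes off the protein")
            frames[fi, n_atoms + pi] = pos

    n_total = n_atoms + truth.n_probes
    return Trajectory(
        coords=frames,
        atom_names=np.array(["CA"] * n_atoms + ["C1"] * truth.n_probes),
        elements=np.array(["C"] * n_total),
        res_ids=np.arange(1, n_total + 1),
        res_names=np.array(["ALA"] * n_atoms + ["PRB"] * truth.n_probes),
        box=box,
    )


# ---------------------------------------------------------------------------
# The synthetic P-series study
# ---------------------------------------------------------------------------

# Synthetic wild-type VH sequence (Kabat-numbered).  This is a VH3-consensus-
# style stand-in constructed to be consistent with every documented sequence
# constraint of the P-series lineage: the wild-type identities implied by the
# reversion-mutant names (L11, E45, S50, S52, S62, D72, S82b, E98, G100d,
# V100f, V100g, I100h), an Abeta(33-42) = GLMVGGVVIA graft occupying Kabat
# 100-100i in CDR3, no N-linked sequon anywhere in the wild type, and the
# D72N mutation creating exactly one sequon (N72-S73-T74).
SYNTHETIC_WT_RESIDUES: tuple[tuple[str, str], ...] = (
    ("1", "E"), ("2", "V"), ("3", "Q"), ("4", "L"), ("5", "V"), ("6", "E"),
    ("7", "S"), ("8", "G"), ("9", "G"), ("10", "G"), ("11", "L"), ("12", "V"),
    ("13", "Q"), ("14", "P"), ("15", "G"), ("16", "G"), ("17", "S"), ("18", "L"),
    ("19", "R"), ("20", "L"), ("21", "S"), ("22", "C"), ("23", "A"), ("24", "A"),
    ("25", "S"), ("26", "G"), ("27", "F"), ("28", "T"), ("29", "F"), ("30", "S"),
    ("31", "S"), ("32", "Y"), ("33", "A"), ("34", "M"), ("35", "S"),
    ("36", "W"), ("37", "V"), ("38", "R"), ("39", "Q"), ("40", "A"), ("41", "P"),
    ("42", "G"), ("43", "K"), ("44", "G"), ("45", "E"), ("46", "L"), ("47", "W"),
    ("48", "V"), ("49", "A"),
    ("50", "S"), ("51", "I"), ("52", "S"), ("53", "G"), ("54", "S"), ("55", "G"),
    ("56", "G"), ("57", "S"), ("58", "T"), ("59", "Y"), ("60", "Y"), ("61", "A"),
    ("62", "S"), ("63", "S"), ("64", "V"), ("65", "K"),
    ("66", "G"), ("67", "R"), ("68", "F"), ("69", "T"), ("70", "I"),
    ("71", "S"), ("72", "D"), ("73", "S"), ("74", "T"), ("75", "S"), ("76", "K"),
    ("77", "N"), ("78", "T"),
    ("79", "L"), ("80", "Y"), ("81", "L"), ("82", "Q"), ("82a", "M"),
    ("82b", "S"), ("82c", "S"), ("83", "L"), ("84", "R"), ("85", "A"),
    ("86", "E"), ("87", "D"), ("88", "T"), ("89", "A"), ("90", "V"),
    ("91", "Y"), ("92", "Y"), ("93", "C"), ("94", "A"),
    ("95", "A"), ("96", "K"), ("97", "G"), ("98", "E"), ("99", "G"),
    ("100", "G"), ("100a", "L"), ("100b", "M"), ("100c", "V"), ("100d", "G"),
    ("100e", "G"), ("100f", "V"), ("100g", "V"), ("100h", "I"), ("100i", "A"),
    ("101", "D"), ("102", "Y"),
    ("103", "W"), ("104", "G"), ("105", "Q"), ("106", "G"), ("107", "T"),
    ("108", "L"), ("109", "V"), ("110", "T"), ("111", "V"), ("112", "S"),
    ("113", "S"),
)

# Forward mutations acquired at each round, relative to the previous round.
PSERIES_MUTATIONS: dict[str, tuple[str, ...]] = {
    "P1": ("L11P", "E45K", "S82bG", "G100dR"),
    "P2": ("S52H", "S62R", "D72N"),
    "P3": ("S50R", "I100hT"),
    "P4": ("E98K", "V100fI", "V100gI"),
}
SIXMUT_MUTATIONS: tuple[str, ...] = ("E45K", "S50R", "S62R", "D72N", "E98K", "G100dR")

# Generating affinities [1/M]; None = below the detection range of the assay
# (modelled as K_D = 1e-2 M, far above the tested concentrations).
AFFINITY_TRUTH_PER_M: dict[str, float | None] = {
    "WT": None,
    "P1": None, "P1-L11": None, "P1-E45": None, "P1-S82b": None, "P1-G100d": None,
    "P2": 1.0e6, "P2-S52": 1.0e6, "P2-S62": None, "P2-D72": None,
    "P3": 4.0e6, "P3-S50": 1.0e6, "P3-I100h": 4.0e6,
    "P4": 2.0e7,
    "P4-L11": 2.0e7, "P4-E45": 4.0e6, "P4-S52": 2.0e7, "P4-S50": 3.0e6,
    "P4-S62": 2.5e6, "P4-D72": 5.0e6, "P4-S82b": 2.0e7, "P4-E98": 8.0e6,
    "P4-G100d": 5.0e5, "P4-V100f": 2.0e7, "P4-V100g": 2.0e7, "P4-I100h": 2.0e7,
    "SIXMUT": 5.0e6,
}

# Generating apparent melting temperatures [degC].  Values for WT, P1-P4, the
# P1 E45 reversion, the P4 E98 reversion and the six-mutation scaffold are the
# study's reported anchors; the remaining reversion constructs carry values
# chosen to realise the qualitative stabilizing/neutral/destabilizing pattern.
TM_TRUTH_C: dict[str, float] = {
    "WT": 75.0,
    "P1": 73.2, "P1-L11": 75.7, "P1-E45": 70.9, "P1-S82b": 73.2, "P1-G100d": 73.2,
    "P2": 65.5, "P2-S52": 65.5, "P2-S62": 68.5, "P2-D72": 69.5,
    "P3": 63.3, "P3-S50": 66.3, "P3-I100h": 63.3,
    "P4": 66.0,
    "P4-L11": 68.5, "P4-E45": 63.5, "P4-S52": 68.5, "P4-S50": 69.0,
    "P4-S62": 69.5, "P4-D72": 70.5, "P4-S82b": 66.0, "P4-E98": 62.4,
    "P4-G100d": 66.0, "P4-V100f": 66.0, "P4-V100g": 66.0, "P4-I100h": 66.0,
    "SIXMUT": 70.5,
}

UNMEASURABLE_KD_M = 1e-2
BUNDLE_LADDER_M = tuple(10.0 ** np.arange(-9.0, -4.4, 0.5))


def synthetic_wildtype() -> VhVariant:
    from .kabat import parse_kabat_position

    return VhVariant(
        name="WT",
        residues=tuple(
            (parse_kabat_position(p), aa) for p, aa in SYNTHETIC_WT_RESIDUES
        ),
    )


def build_pseries_lineage() -> dict[str, VhVariant]:
    """WT, P1-P4, the per-round single-reversion constructs, and the
    six-affinity-mutation scaffold (SIXMUT)."""
    variants: dict[str, VhVariant] = {"WT": synthetic_wildtype()}
    parent = "WT"
    for name, muts in PSERIES_MUTATIONS.items():
        variants[name] = apply_mutations(
            variants[parent], tuple(parse_mutation(m) for m in muts), name=name
        )
        parent = name
    # single reversions probed in the context of P4 cover all twelve mutations;
    # earlier contexts probe only their newly acquired mutations
    probed = {
        "P1": PSERIES_MUTATIONS["P1"],
        "P2": PSERIES_MUTATIONS["P2"],
        "P3": PSERIES_MUTATIONS["P3"],
        "P4": tuple(m for round_ in PSERIES_MUTATIONS.values() for m in round_),
    }
    for context, muts in probed.items():
        for m in muts:
            fwd = parse_mutation(m)
            rev = fwd.reverse()
            name = f"{context}-{rev.to_aa}{rev.position}"
            variants[name] = apply_mutations(variants[context], (rev,), name=name)
    variants["SIXMUT"] = apply_mutations(
        variants["WT"],
        tuple(parse_mutation(m) for m in SIXMUT_MUTATIONS),
        name="SIXMUT",
    )
    return variants


def _truth_class(ctx: float | None, rev: float | None, positive: str, negative: str) -> str:
    if ctx is None or rev is None:
        return NOT_COMPUTABLE
    if ctx == rev:
        return "neutral"
    return positive if ctx > rev else negative


@dataclass(frozen=True)
class PseriesBundle:
    """In-memory synthetic study: lineage, raw CSV tables and truth sidecar."""

    lineage: dict[str, VhVariant]
    titrations: pd.DataFrame
    melts: pd.DataFrame
    truth: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "lineage.json", "w") as fh:
            json.dump(lineage_to_dict(list(self.lineage.values())), fh, indent=1)
        self.titrations.to_csv(out / "titrations.csv", index=False)
        self.melts.to_csv(out / "melts.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1)


def gen_pseries_bundle(
    seed: int,
    titration_noise_sd: float = 20.0,
    melt_noise_sd: float = 0.3,
    n_affinity_replicates: int = 3,
    n_melt_replicates: int = 2,
) -> PseriesBundle:
    """Generate the full synthetic affinity-maturation study.

    The generating truths follow the study's qualitative pattern: the P1
    branch is below the affinity detection range, R50/R62/N72 are
    affinity-enhancing but destabilizing, K45/K98 are enhancing and
    stabilizing, R100d is enhancing and stability-neutral, and
    P11/H52/G82b/I100f/I100g/T100h are affinity-neutral.
    """
    lineage = build_pseries_lineage()
    names = sorted(AFFINITY_TRUTH_PER_M)
    t_rows, m_rows = [], []
    for vi, name in enumerate(names):
        ka = AFFINITY_TRUTH_PER_M[name]
        kd = UNMEASURABLE_KD_M if ka is None else 1.0 / ka
        ttruth = TitrationTruth(
            variant=name,
            kd=kd,
            concentrations=BUNDLE_LADDER_M,
            noise_sd=titration_noise_sd,
            n_replicates=n_affinity_replicates,
            seed=seed,
        )
        for ds in gen_titration(ttruth, stream=vi):
            for c, s in ds.points:
                t_rows.append(
                    {"variant": name, "replicate": ds.replicate_id, "conc_M": c, "signal": s}
                )
        mtruth = MeltTruth(
            variant=name,
            tm=TM_TRUTH_C[name],
            noise_sd=melt_noise_sd,
            n_replicates=n_melt_replicates,
            seed=seed,
        )
        for rep, curve in enumerate(gen_melt(mtruth, stream=vi)):
            for t, s in curve.points:
                m_rows.append(
                    {"variant": name, "replicate": rep, "scan": 1, "temp_C": t, "signal": s}
                )

    records = []
    for name, variant in lineage.items():
        if variant.parent in PSERIES_MUTATIONS or variant.parent == "P4":
            if len(variant.mutations_from_parent) != 1 or variant.parent not in lineage:
                continue
            rev = variant.mutations_from_parent[0]
            fwd = rev.reverse()
            records.append(
                {
                    "context": variant.parent,
                    "label": f"{fwd.to_aa}{fwd.position}",
                    "affinity_class": _truth_class(
                        AFFINITY_TRUTH_PER_M[variant.parent],
                        AFFINITY_TRUTH_PER_M[name],
                        "enhancing",
                        "reducing",
                    ),
                    "stability_class": _truth_class(
                        TM_TRUTH_C[variant.parent],
                        TM_TRUTH_C[name],
                        "stabilizing",
                        "destabilizing",
                    ),
                }
            )

    truth = {
        "seed": seed,
        "noise": {
            "titration_sd_au": titration_noise_sd,
            "melt_sd_mdeg": melt_noise_sd,
        },
        "variants": {
            name: {"ka_per_M": AFFINITY_TRUTH_PER_M[name], "tm_C": TM_TRUTH_C[name]}
            for name in names
        },
        "records": records,
    }
    return PseriesBundle(
        lineage=lineage,
        titrations=pd.DataFrame(t_rows),
        melts=pd.DataFrame(m_rows),
        truth=truth,
    )
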