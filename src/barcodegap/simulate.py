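"""Synthetic two-locus barcode datasets with planted cryptic structure.

Sequences evolve under the Kimura two-parameter substitution process: a
continuous-time Markov chain on {A, C, G, T} with transition rate alpha
and transversion rate beta per target (kappa = alpha/beta, default 2),
normalised so branch lengths are expected substitutions per site.  Each
site's end state is drawn from the exact K2P transition probabilities

    P_ts(t)      = 1/4 + 1/4 e^{-4 beta t} - 1/2 e^{-2(alpha+beta) t}
    P_tv(t) each = 1/4 - 1/4 e^{-4 beta t}

so the simulation is exact (the endpoint law of the CTMC) and the
analytic expectation doubles as the test oracle: the K2P distance
estimator applied to a pair separated by total branch length t has
expectation t.

Planted divergences are given on the percent scale users think in.  A
morphospecies with clades at planted intra-clade divergence d_w and
inter-clade divergence d_b is built star-wise: each clade ancestor sits
(d_b - d_w)/2 from the root, each specimen d_w/2 from its ancestor, so
expected pairwise K2P is d_w within and d_b between clades.  Per-locus
rate multipliers (COI faster than 16S, default 3:1) scale every branch.
No indels are simulated: alignments are gap-free by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import LOCI, LocusAlignment, SpecimenRecord

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulatedDataset",
    "evolve",
    "random_root",
    "simulate_dataset",
    "simulate_scenario_suite",
]

# Beyond ~3 expected substitutions per site the distance estimator is
# effectively always saturated; refuse to plant such divergences.
MAX_PLANTED = 3.0


class ConfigError(ValueError):
    """Invalid or unreachable simulation settings."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped defaults: a handful of morphospecies each holding
    1-3 clades, COI ~660 bp / 16S ~500 bp, COI evolving 3x faster, a
    clean cryptic separation (intra below 1%, inter an order of
    magnitude above), and ragged per-locus specimen coverage (16S
    recovered more often than COI).
    """

    n_morphospecies: int = 5
    clades_per_morphospecies: tuple[int, ...] = (3, 2, 1, 2, 1)
    specimens_per_clade: int = 5
    locus_length: dict = field(
        default_factory=lambda: {"COI": 660, "16S": 500}
    )
    rate_multiplier: dict = field(
        default_factory=lambda: {"COI": 1.0, "16S": 1.0 / 3.0}
    )
    kappa: float = 2.0
    # planted pairwise K2P percentages on the COI scale; other loci are
    # scaled by their rate multiplier
    inter_pct: float = 12.0
    intra_pct: float = 0.5
    # per-locus planted (intra_pct, inter_pct) overrides, bypassing the
    # rate multiplier — used to decouple loci (e.g. a 16S that never
    # crosses the clade threshold)
    planted_override: dict = field(default_factory=dict)
    locus_fraction: dict = field(
        default_factory=lambda: {"COI": 0.6, "16S": 0.95}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_morphospecies < 1 or self.specimens_per_clade < 1:
            raise ConfigError("counts must be >= 1")
        if len(self.clades_per_morphospecies) != self.n_morphospecies:
            raise ConfigError("need one clade count per morphospecies")
        if any(c < 1 for c in self.clades_per_morphospecies):
            raise ConfigError("clade counts must be >= 1")
        if self.kappa <= 0:
            raise ConfigError("kappa must be positive")
        for frac in self.locus_fraction.values():
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("locus fractions must lie in [0, 1]")
        for locus in LOCI:
            intra, inter = self.planted_for(locus)
            if intra < 0 or inter < intra:
                raise ConfigError(
                    f"{locus}: planted inter must be >= intra >= 0 "
                    f"(got intra={intra}%, inter={inter}%)"
                )
            if inter / 100.0 > MAX_PLANTED:
                raise ConfigError(
                    f"{locus}: planted divergence {inter}% is beyond saturation"
                )

    def planted_for(self, locus: str) -> tuple[float, float]:
        """(intra %, inter %) planted at one locus."""
        if locus in self.planted_override:
            return tuple(self.planted_override[locus])
        mult = self.rate_multiplier[locus]
        return self.intra_pct * mult, self.inter_pct * mult


@dataclass
class SimulationTruth:
    """Planted ground truth: clade of each specimen, per-morphospecies
    intended scenario and planted divergences."""

    clade_of: dict[str, str]
    scenario_of: dict[str, str]
    planted: dict[str, dict[str, tuple[float, float]]]

    def clades_in(self, morphospecies: str) -> dict[str, set]:
        out: dict[str, set] = {}
        for sid, clade in self.clade_of.items():
            if clade.startswith(morphospecies + "/"):
                out.setdefault(clade, set()).add(sid)
        return out


@dataclass
class SimulatedDataset:
    alignments: dict[str, LocusAlignment]
    records: dict[str, SpecimenRecord]
    truth: SimulationTruth
    config: SimulationConfig


def _k2p_probs(t: float, kappa: float) -> tuple[float, float]:
    """(P_transition, P_each_transversion) after branch length t."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e4b = np.exp(-4.0 * beta * t)
    e2ab = np.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e4b - 0.5 * e2ab
    p_tv = 0.25 - 0.25 * e4b
    return float(p_ts), float(p_tv)


def evolve(parent: np.ndarray, t: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve coded sequences along a branch of t expected subs/site.

    parent is a uint8 array (codes A=0, C=1, G=2, T=3) of any shape.
    With this coding a transition is XOR 2 and the two transversions are
    XOR 1 and XOR 3, so mutation is a vectorised XOR with a category
    drawn per site from the exact endpoint distribution.
    """
    if t < 0:
        raise ConfigError("negative branch length")
    if t == 0:
        return parent.copy()
    p_ts, p_tv = _k2p_probs(t, kappa)
    u = rng.random(parent.shape)
    xor = np.zeros(parent.shape, dtype=np.uint8)
    xor[u < p_ts] = 2
    xor[(u >= p_ts) & (u < p_ts + p_tv)] = 1
    xor[(u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)] = 3
    return parent ^ xor


def random_root(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


_DECODE = np.array(list("ACGT"))


def _to_str(codes: np.ndarray) -> str:
    return "".join(_DECODE[codes])


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate aligned sequences, specimen metadata and ground truth.

    Fully determined by config (including its seed): the same config
    yields byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    clade_of: dict[str, str] = {}
    planted: dict[str, dict[str, tuple[float, float]]] = {}
    records: dict[str, SpecimenRecord] = {}
    per_locus_rows: dict[str, list[tuple[str, str]]] = {l: [] for l in LOCI}

    # decide locus availability first so sequence draws stay aligned
    # with specimen identity regardless of locus fractions
    for m in range(config.n_morphospecies):
        morph = f"sp{m + 1:02d}"
        planted[morph] = {l: config.planted_for(l) for l in LOCI}
        n_clades = config.clades_per_morphospecies[m]
        specimen_meta: list[tuple[str, str, frozenset]] = []
        for c in range(n_clades):
            for s in range(config.specimens_per_clade):
                sid = f"{morph}c{c + 1}s{s + 1:02d}"
                present = set()
                for locus in LOCI:
                    if rng.random() < config.locus_fraction.get(locus, 1.0):
                        present.add(locus)
                if not present:  # every specimen was sequenced at >=1 locus
                    present.add("16S")
                clade_of[sid] = f"{morph}/clade{c + 1}"
                specimen_meta.append((sid, f"clade{c + 1}", frozenset(present)))
                records[sid] = SpecimenRecord(
                    specimen_id=sid,
                    morphospecies=morph,
                    loci_present=frozenset(present),
                    site=None,
                )
        for locus in LOCI:
            intra_pct, inter_pct = planted[morph][locus]
            d_w = intra_pct / 100.0
            d_b = inter_pct / 100.0
            t_anc = (d_b - d_w) / 2.0
            t_tip = d_w / 2.0
            root = random_root(config.locus_length[locus], rng)
            ancestors = {
                f"clade{c + 1}": evolve(root, t_anc, config.kappa, rng)
                for c in range(n_clades)
            }
            for sid, clade, present in specimen_meta:
                seq = evolve(ancestors[clade], t_tip, config.kappa, rng)
                if locus in present:
                    per_locus_rows[locus].append((sid, _to_str(seq)))

    alignments = {
        locus: LocusAlignment(
            locus=locus,
            ids=[sid for sid, _ in rows],
            sequences=[s for _, s in rows],
        )
        for locus, rows in per_locus_rows.items()
        if rows
    }
    scenario_of = {m: _intended_scenario(cfg=config, morph=m) for m in planted}
    truth = SimulationTruth(
        clade_of=clade_of, scenario_of=scenario_of, planted=planted
    )
    return SimulatedDataset(
        alignments=alignments, records=records, truth=truth, config=config
    )


def _intended_scenario(cfg: SimulationConfig, morph: str) -> str:
    """The scenario the planted settings aim at (coarse; suite configs
    below are the authoritative per-scenario generators)."""
    idx = int(morph[2:]) - 1
    if cfg.clades_per_morphospecies[idx] == 1:
        return "S4"
    return "S1"


def scenario_config(scenario: str, seed: int, specimens_per_clade: int = 5) -> SimulationConfig:
    """Planted settings that realise one evidence scenario.

    S1: clean separation at both loci.  S2: COI separates, 16S planted
    below its clade threshold so clades merge.  S3: 16S-only signal with
    intra- and inter-clade variation that genuinely overlap (an
    unresolved species complex).  S4: a single clade.

    Suite bundles use denser locus coverage than the ragged survey-like
    default so every planted clade is actually sampled at the
    discriminating locus: the bundles test the classifier, not the
    sampling design.
    """
    base = dict(
        n_morphospecies=1,
        specimens_per_clade=specimens_per_clade,
        seed=seed,
        locus_fraction={"COI": 0.8, "16S": 1.0},
    )
    if scenario == "S1":
        return SimulationConfig(
            clades_per_morphospecies=(3,), inter_pct=12.0, intra_pct=0.5, **base
        )
    if scenario == "S2":
        return SimulationConfig(
            clades_per_morphospecies=(2,),
            inter_pct=12.0,
            intra_pct=0.5,
            planted_override={"16S": (0.15, 0.4)},
            **base,
        )
    if scenario == "S3":
        base["locus_fraction"] = {"COI": 0.0, "16S": 1.0}
        return SimulationConfig(
            clades_per_morphospecies=(2,),
            planted_override={"16S": (3.0, 5.0)},  # overlapping intra/inter
            **base,
        )
    if scenario == "S4":
        return SimulationConfig(
            clades_per_morphospecies=(1,), inter_pct=0.5, intra_pct=0.5, **base
        )
    raise ConfigError(f"unknown scenario {scenario!r}")


def simulate_scenario_suite(seed: int, specimens_per_clade: int = 5) -> dict[str, SimulatedDataset]:
    """One labelled dataset per evidence scenario, for end-to-end tests."""
    out: dict[str, SimulatedDataset] = {}
    for i, scenario in enumerate(("S1", "S2", "S3", "S4")):
        cfg = scenario_config(scenario, seed=seed * 4 + i,
                              specimens_per_clade=specimens_per_clade)
        ds = simulate_dataset(cfg)
        for morph in ds.truth.scenario_of:
            ds.truth.scenario_of[morph] = scenario
        out[scenario] = ds
    return out
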