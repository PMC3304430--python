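"""Seeded generator of every input the pipeline consumes, with ground truth.

The generator emulates the statistical structure of a two-species xenograft
chip experiment: two probe universes with a configurable ortholog pairing, a
fraction of cross-hybridising probe sets that leak a ``kappa``-scaled copy of
their ortholog's linear signal onto the other chip, treatment effects planted
in named gene sets (NF-kB / TNF / IL-6 / IFN-beta style target sets) on a
5-vs-5 group design, cytokine protein levels coupled to the planted RNA fold
changes with optional post-transcriptional amplification, piecewise tumour
growth with treatment-induced regression, and necrosis masks of known area
fraction.

Leakage is additive in linear intensity space (hybridisation signal is
additive in bound target); planted effects are specified in log2 space for
the species' own transcripts.  All randomness flows from one root seed
through named substreams (universe, arrays, cytokines, growth, masks) so each
component can be regenerated independently and everything is deterministic
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .iotables import (
    HUMAN,
    MOUSE,
    OrthologMap,
    ProbeIntensityMatrix,
    ProbesetMap,
    SampleSheet,
    GeneSetCollection,
)

_STREAMS = {"universe": 0, "arrays": 1, "cytokines": 2, "growth": 3, "masks": 4}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG of the root seed; streams are mutually independent."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[name],))
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreatmentSet:
    """A gene set carrying a planted treatment effect.

    Per member probe set the true log2 fold change is drawn once from
    N(effect_mean, effect_sd^2), independently per species.
    """

    name: str
    n_genes: int
    effect_mean: float  # log2 units
    effect_sd: float = 0.3


@dataclass(frozen=True)
class AnalyteSpec:
    """One cytokine analyte of the multiplex panel.

    ``induced`` analytes are assigned a gene inside a treatment set (so their
    transcript responds); non-induced ones a gene outside all treatment sets.
    ``gamma`` is the post-transcriptional amplification: the true protein
    fold change is (RNA fold) x gamma, so gamma > 1 with an unchanged
    transcript models post-transcriptional regulation (the G-CSF pattern).
    """

    name: str
    species: str
    gamma: float = 1.0
    induced: bool = True
    baseline_pg_per_ml: float = 50.0


@dataclass(frozen=True)
class GrowthModel:
    """Piecewise tumour growth: exponential growth; treated tumours regress
    to fraction ``regression_fraction`` of their pre-treatment volume over
    ``regression_days`` days, then regrow exponentially.

    The treated arm's relative volume is f^(t/d) for t <= d and
    f * exp(g' (t - d)) afterwards; the analytic time of return to the
    pre-treatment volume is d + ln(1/f) / g'.
    """

    growth_rate: float = 0.08          # per day, untreated
    regression_fraction: float = 0.3   # f
    regression_days: float = 4.0       # d
    regrowth_rate: float = 0.055       # g', per day
    n_per_group: int = 6
    study_days: int = 42
    start_diameter_mm: float = 3.5
    aspect_ratio: float = 0.8          # minor / major axis
    noise_sd: float = 0.1              # lognormal sd on volume; 0 = exact
    v0_cv: float = 0.15                # between-mouse spread of start volume

    @property
    def crossing_time(self) -> float:
        """Analytic day on which the treated arm returns to V(0)."""
        return self.regression_days + np.log(1.0 / self.regression_fraction) / self.regrowth_rate


@dataclass(frozen=True)
class NecrosisMaskSpec:
    target_fraction: float = 0.34
    height: int = 512
    width: int = 512
    um_per_pixel: float = 2.0
    blob_radius_px: tuple[int, int] = (8, 40)
    tolerance: float = 0.01
    max_iter: int = 10000


def _default_treatment_sets() -> tuple[TreatmentSet, ...]:
    return (
        TreatmentSet("NFKB_TARGETS", 40, 1.2, 0.3),
        TreatmentSet("TNF_TARGETS", 30, 1.0, 0.3),
        TreatmentSet("IL6_TARGETS", 30, 0.9, 0.3),
        TreatmentSet("IFNB_TARGETS", 25, 1.0, 0.3),
    )


def _default_cytokines() -> tuple[AnalyteSpec, ...]:
    # Panel modelled on a species-resolved multiplex assay: transcriptionally
    # induced chemokines plus post-transcriptionally amplified analytes, the
    # extreme case being a G-CSF-like analyte with unchanged mRNA.
    return (
        AnalyteSpec("MCP1_like", MOUSE, gamma=1.0, induced=True),
        AnalyteSpec("IL6_like", MOUSE, gamma=1.0, induced=True),
        AnalyteSpec("IP10_like", MOUSE, gamma=1.0, induced=True),
        AnalyteSpec("TNFA_like", MOUSE, gamma=10.0, induced=False),
        AnalyteSpec("GCSF_like", MOUSE, gamma=68.0, induced=False),
        AnalyteSpec("IL8_like", HUMAN, gamma=1.0, induced=True),
        AnalyteSpec("GMCSF_like", HUMAN, gamma=1.0, induced=True),
        AnalyteSpec("EGF_like", HUMAN, gamma=1.0, induced=False),
    )


@dataclass(frozen=True)
class SynthConfig:
    """Full specification of a synthetic xenograft study."""

    seed: int = 0
    n_probesets: int = 1000
    probes_per_set: int = 11
    ortholog_fraction: float = 0.8
    crosshyb_fraction: float = 0.15   # rho; echoes the 14-16% seen on real chips
    kappa: float = 0.5                # leakage coefficient, linear scale
    n_per_group: int = 5
    n_control_replicates: int = 2
    est_fraction: float = 0.5         # of non-ortholog probe sets left unannotated
    absent_fraction: float = 0.0      # probe sets whose transcript is not expressed
    absent_log2: float = -10.0        # effective baseline of absent transcripts
    treatment_sets: tuple[TreatmentSet, ...] = field(default_factory=_default_treatment_sets)
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    affinity_sd: float = 0.7          # fixed per-probe offset, log2 units
    noise_sd: float = 0.25            # per-observation measurement noise, log2 units
    background_mean: float = 64.0     # linear scale
    background_sd: float = 16.0
    cytokines: tuple[AnalyteSpec, ...] = field(default_factory=_default_cytokines)
    n_mice_per_group: int = 3         # cytokine panel animals
    cytokine_noise_sd: float = 0.15   # lognormal (natural-log) sd on concentrations
    extract_volume_ml: float = 0.2    # homogenisation volume
    tumour_mass_g: float = 0.3
    lod_pg_per_ml: float = 3.2
    growth: GrowthModel = field(default_factory=GrowthModel)
    necrosis: NecrosisMaskSpec = field(default_factory=NecrosisMaskSpec)

    def __post_init__(self) -> None:
        for name in ("ortholog_fraction", "crosshyb_fraction", "kappa", "est_fraction",
                     "absent_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("baseline_log2_sd", "affinity_sd", "noise_sd", "background_sd",
                     "cytokine_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_probesets < 1 or self.probes_per_set < 1:
            raise ValueError("universe dimensions must be positive")

    def with_(self, **kwargs) -> "SynthConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class SynthTruth:
    """Planted ground truth retained for recovery tests."""

    crosshyb_sets: dict[str, set[str]]                 # species -> probe set ids
    true_log2fc: dict[str, dict[str, float]]           # species -> probe set -> log2 fc
    baseline_log2: dict[str, dict[str, float]]         # species -> probe set -> baseline
    symbol_to_probeset: dict[str, dict[str, str]]      # species -> symbol -> probe set
    ortholog_pairs: list[tuple[str, str]]              # (human symbol, mouse symbol)
    treatment_membership: dict[str, dict[str, list[str]]]  # species -> set name -> symbols
    absent_sets: dict[str, set[str]] = field(default_factory=dict)  # unexpressed
    analytes: pd.DataFrame | None = None               # per-analyte truth
    necrosis_fraction: float | None = None
    growth: pd.DataFrame | None = None                 # noise-free group-mean curves
    growth_crossing_time: float | None = None
    growth_expected_measured_delay: float | None = None

    def rna_fold(self, species: str, gene_symbol: str) -> float:
        ps = self.symbol_to_probeset[species].get(gene_symbol)
        if ps is None:
            return 1.0
        return float(2.0 ** self.true_log2fc[species].get(ps, 0.0))


@dataclass
class Universe:
    """Probe universes of both species plus the planted truth."""

    probeset_maps: dict[str, ProbesetMap]
    ortholog_map: OrthologMap
    gene_sets: dict[str, GeneSetCollection]   # species -> treatment-set collection
    truth: SynthTruth
    probe_affinity: dict[str, dict[str, float]]   # species -> probe -> log2 offset
    config: SynthConfig


# ---------------------------------------------------------------------------
# Universe
# ---------------------------------------------------------------------------

def _probeset_id(species: str, i: int) -> str:
    prefix = "HS" if species == HUMAN else "MM"
    return f"{prefix}_{i:05d}_at"


def generate_universe(config: SynthConfig) -> Universe:
    """Build both species' probe universes, the ortholog pairing and truth.

    Cross-hybridising probe sets are drawn (independently per species) from
    the ortholog-paired ones, since leakage needs an orthologous transcript
    to leak from.  Treatment-set members and induced cytokine genes are
    likewise assigned among orthologous genes so both chips see the effects.
    """
    rng = substream(config.seed, "universe")
    n = config.n_probesets
    n_orth = int(round(config.ortholog_fraction * n))
    n_cross = int(round(config.crosshyb_fraction * n))
    if n_cross > n_orth:
        raise ValueError("crosshyb_fraction cannot exceed ortholog_fraction")

    probeset_ids = {sp: [_probeset_id(sp, i) for i in range(n)] for sp in (HUMAN, MOUSE)}
    # orthologous genes occupy slots [0, n_orth); symbol case follows convention
    ortholog_pairs = [(f"GENE{i:04d}", f"Gene{i:04d}") for i in range(n_orth)]
    symbols: dict[str, dict[str, str]] = {HUMAN: {}, MOUSE: {}}  # probeset -> symbol
    for i, (hu, mo) in enumerate(ortholog_pairs):
        symbols[HUMAN][probeset_ids[HUMAN][i]] = hu
        symbols[MOUSE][probeset_ids[MOUSE][i]] = mo
    for sp in (HUMAN, MOUSE):
        rest = probeset_ids[sp][n_orth:]
        n_est = int(round(config.est_fraction * len(rest)))
        for j, ps in enumerate(rest[n_est:]):
            base = f"SOLO{j:04d}"
            symbols[sp][ps] = base if sp == HUMAN else base.capitalize()
        # remaining probe sets stay unannotated (uncharacterised ESTs)

    # treatment-set membership over orthologous gene slots, disjoint sets
    slots = rng.permutation(n_orth)
    cursor = 0
    membership: dict[str, dict[str, list[str]]] = {HUMAN: {}, MOUSE: {}}
    member_slots: dict[str, list[int]] = {}
    for ts in config.treatment_sets:
        take = slots[cursor:cursor + ts.n_genes]
        if len(take) < ts.n_genes:
            raise ValueError("not enough orthologous genes for the treatment sets")
        cursor += ts.n_genes
        member_slots[ts.name] = list(take)
        membership[HUMAN][ts.name] = [ortholog_pairs[i][0] for i in take]
        membership[MOUSE][ts.name] = [ortholog_pairs[i][1] for i in take]
    free_slots = [int(s) for s in slots[cursor:]]

    # planted per-probe-set log2 effects, drawn independently per species
    true_fc: dict[str, dict[str, float]] = {
        sp: {ps: 0.0 for ps in probeset_ids[sp]} for sp in (HUMAN, MOUSE)
    }
    for ts in config.treatment_sets:
        for sp in (HUMAN, MOUSE):
            for slot in member_slots[ts.name]:
                eff = rng.normal(ts.effect_mean, ts.effect_sd)
                true_fc[sp][probeset_ids[sp][slot]] = float(eff)

    # cross-hybridising probe sets, per species, among orthologous slots
    crosshyb: dict[str, set[str]] = {}
    crosshyb_slots: set[int] = set()
    for sp in (HUMAN, MOUSE):
        chosen = rng.choice(n_orth, size=n_cross, replace=False)
        crosshyb[sp] = {probeset_ids[sp][i] for i in chosen}
        crosshyb_slots |= {int(i) for i in chosen}

    # absent (unexpressed) probe sets: never treatment members, never
    # cross-hybridising and never the ortholog partner of one (a leaking
    # ortholog must be present to leak)
    absent: dict[str, set[str]] = {sp: set() for sp in (HUMAN, MOUSE)}
    if config.absent_fraction > 0:
        n_absent = int(round(config.absent_fraction * n))
        member_all = {s for slots_ in member_slots.values() for s in slots_}
        eligible = [
            i for i in range(n)
            if i not in member_all and i not in crosshyb_slots
        ]
        if n_absent > len(eligible):
            raise ValueError("absent_fraction too large for this universe")
        for sp in (HUMAN, MOUSE):
            chosen = rng.choice(len(eligible), size=n_absent, replace=False)
            absent[sp] = {probeset_ids[sp][eligible[int(i)]] for i in chosen}

    # baselines and probe affinities
    baseline: dict[str, dict[str, float]] = {}
    affinity: dict[str, dict[str, float]] = {}
    probe_maps: dict[str, ProbesetMap] = {}
    for sp in (HUMAN, MOUSE):
        baseline[sp] = {
            ps: (config.absent_log2 if ps in absent[sp]
                 else float(rng.normal(config.baseline_log2_mean, config.baseline_log2_sd)))
            for ps in probeset_ids[sp]
        }
        probe_to_set: dict[str, str] = {}
        aff: dict[str, float] = {}
        for ps in probeset_ids[sp]:
            for j in range(config.probes_per_set):
                probe = f"{ps}:p{j:02d}"
                probe_to_set[probe] = ps
                aff[probe] = float(rng.normal(0.0, config.affinity_sd))
        affinity[sp] = aff
        probe_maps[sp] = ProbesetMap(sp, probe_to_set, dict(symbols[sp]))

    truth = SynthTruth(
        crosshyb_sets=crosshyb,
        true_log2fc=true_fc,
        baseline_log2=baseline,
        symbol_to_probeset={
            sp: {sym: ps for ps, sym in symbols[sp].items()} for sp in (HUMAN, MOUSE)
        },
        ortholog_pairs=ortholog_pairs,
        treatment_membership=membership,
        absent_sets=absent,
    )
    # stash free orthologous slots for the cytokine generator
    truth.analytes = None
    truth._free_slots = free_slots  # type: ignore[attr-defined]

    gene_sets = {
        sp: GeneSetCollection({ts.name: set(membership[sp][ts.name])
                               for ts in config.treatment_sets}, species=sp)
        for sp in (HUMAN, MOUSE)
    }
    om = OrthologMap(list(ortholog_pairs))
    return Universe(probe_maps, om, gene_sets, truth, affinity, config)


# ---------------------------------------------------------------------------
# Array generation
# ---------------------------------------------------------------------------

def _other(species: str) -> str:
    return MOUSE if species == HUMAN else HUMAN


def _chip_vectors(universe: Universe, chip: str) -> dict[str, np.ndarray]:
    """Per-probe vectors of the signal model for one chip, cached."""
    cache = getattr(universe, "_vec_cache", None)
    if cache is None:
        cache = universe._vec_cache = {}  # type: ignore[attr-defined]
    if chip in cache:
        return cache[chip]
    pm = universe.probeset_maps[chip]
    truth = universe.truth
    probes = list(pm.probe_to_set)
    base = truth.baseline_log2[chip]
    fc = truth.true_log2fc[chip]
    other = _other(chip)
    base_o = truth.baseline_log2[other]
    fc_o = truth.true_log2fc[other]
    om = universe.ortholog_map
    sym_to_ps_o = truth.symbol_to_probeset[other]
    aff = universe.probe_affinity[chip]

    n = len(probes)
    v = {
        "base": np.empty(n), "fc": np.empty(n), "aff": np.empty(n),
        "leak": np.zeros(n, dtype=bool), "base_o": np.zeros(n), "fc_o": np.zeros(n),
    }
    for i, probe in enumerate(probes):
        ps = pm.probe_to_set[probe]
        v["base"][i] = base[ps]
        v["fc"][i] = fc[ps]
        v["aff"][i] = aff[probe]
        if ps in truth.crosshyb_sets[chip]:
            sym = pm.symbol_of(ps)
            orth = om.ortholog(sym, chip) if sym else None
            ps_o = sym_to_ps_o.get(orth) if orth else None
            if ps_o is not None:
                v["leak"][i] = True
                v["base_o"][i] = base_o[ps_o]
                v["fc_o"][i] = fc_o[ps_o]
    cache[chip] = v
    return v


def _linear_signal(
    rng: np.random.Generator,
    config: SynthConfig,
    universe: Universe,
    chip: str,
    treated: bool,
    own_rna: bool,
    other_rna: bool,
) -> np.ndarray:
    """One array of linear probe intensities for the given RNA content.

    Background is drawn per probe; own-species RNA adds 2^(baseline + effect
    + probe affinity + noise); other-species RNA adds kappa-scaled ortholog
    signal, but only to probes of cross-hybridising probe sets.
    """
    v = _chip_vectors(universe, chip)
    n = len(v["base"])
    out = rng.normal(config.background_mean, config.background_sd, size=n)
    own_noise = rng.normal(0.0, config.noise_sd, size=n)
    leak_noise = rng.normal(0.0, config.noise_sd, size=n)
    if own_rna:
        mu = v["base"] + (v["fc"] if treated else 0.0) + v["aff"]
        out = out + 2.0 ** (mu + own_noise)
    if other_rna and config.kappa > 0.0:
        mu = v["base_o"] + (v["fc_o"] if treated else 0.0) + v["aff"]
        out = out + np.where(
            v["leak"], config.kappa * 2.0 ** (mu + leak_noise), 0.0
        )
    return np.maximum(out, 1e-6)


CONTROL_CONFIGS = (
    (HUMAN, "human_only"),
    (HUMAN, "mouse_only"),
    (MOUSE, "mouse_only"),
    (MOUSE, "human_only"),
)


def generate_control_hybs(
    universe: Universe, config: SynthConfig | None = None
) -> dict[tuple[str, str], ProbeIntensityMatrix]:
    """The four control hybridisations: each species' RNA on each chip.

    Keys are (chip_species, rna_source); same-species arrays carry full
    signal, other-species arrays background plus kappa-scaled leakage on the
    cross-hybridising probe sets only.
    """
    config = config or universe.config
    rng = substream(config.seed, "arrays")
    out: dict[tuple[str, str], ProbeIntensityMatrix] = {}
    for chip, rna_source in CONTROL_CONFIGS:
        own = rna_source == f"{chip}_only"
        probes = list(universe.probeset_maps[chip].probe_to_set)
        cols = {}
        for r in range(config.n_control_replicates):
            sid = f"{chip[:2]}chip_{rna_source}_r{r + 1}"
            cols[sid] = _linear_signal(
                rng, config, universe, chip,
                treated=False, own_rna=own, other_rna=not own,
            )
        out[(chip, rna_source)] = ProbeIntensityMatrix(
            chip, pd.DataFrame(cols, index=probes)
        )
    return out


def generate_xenograft_arrays(
    universe: Universe, config: SynthConfig | None = None
) -> tuple[dict[str, ProbeIntensityMatrix], SampleSheet]:
    """Xenograft arrays for both chips: n untreated + n treated per chip.

    Xenograft RNA is a two-species mixture, so every array carries own-species
    signal plus leakage onto cross-hybridising probe sets in *both* groups;
    treated arrays additionally apply the planted log2 effects.
    """
    config = config or universe.config
    rng = substream(config.seed, "arrays")
    # keep the control and xenograft substreams apart
    rng = np.random.default_rng(rng.integers(2**31))
    matrices: dict[str, ProbeIntensityMatrix] = {}
    rows = []
    for chip in (HUMAN, MOUSE):
        probes = list(universe.probeset_maps[chip].probe_to_set)
        cols = {}
        for group in ("untreated", "treated"):
            for r in range(config.n_per_group):
                sid = f"{chip[:2]}chip_xeno_{group}_{r + 1}"
                cols[sid] = _linear_signal(
                    rng, config, universe, chip,
                    treated=group == "treated", own_rna=True, other_rna=True,
                )
                rows.append((sid, chip, "xenograft", group, r + 1))
        matrices[chip] = ProbeIntensityMatrix(chip, pd.DataFrame(cols, index=probes))
    sheet = SampleSheet(pd.DataFrame(
        rows, columns=["sample_id", "chip_species", "rna_source", "group", "replicate"]
    ))
    return matrices, sheet


# ---------------------------------------------------------------------------
# Cytokine panel
# ---------------------------------------------------------------------------

def generate_cytokine_panel(
    universe: Universe, config: SynthConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-analyte concentrations for n mice per group, plus analyte truth.

    Induced analytes are tied to a treatment-set gene, so their true RNA fold
    comes from the planted effect; the true protein fold is RNA fold x gamma.
    Returns (panel rows, analyte truth) and records the truth on the
    universe's SynthTruth.
    """
    config = config or universe.config
    rng = substream(config.seed, "cytokines")
    truth = universe.truth
    free = list(getattr(truth, "_free_slots", []))
    used_genes: set[str] = set()
    panel_rows = []
    truth_rows = []
    for spec in config.cytokines:
        sp = spec.species
        # assign a gene: induced -> member of the first treatment set with a
        # spare gene; non-induced -> orthologous gene outside every set
        gene = None
        if spec.induced:
            for ts in config.treatment_sets:
                for sym in truth.treatment_membership[sp][ts.name]:
                    if sym not in used_genes:
                        gene = sym
                        break
                if gene:
                    break
        else:
            while free:
                slot = free.pop(0)
                cand = truth.ortholog_pairs[slot][0 if sp == HUMAN else 1]
                if cand not in used_genes:
                    gene = cand
                    break
        if gene is None:
            raise ValueError(f"no gene available for analyte {spec.name!r}")
        used_genes.add(gene)
        rna_fold = truth.rna_fold(sp, gene)
        protein_fold = rna_fold * spec.gamma
        for group, fold in (("untreated", 1.0), ("treated", protein_fold)):
            for m in range(config.n_mice_per_group):
                conc = spec.baseline_pg_per_ml * fold * float(
                    np.exp(rng.normal(0.0, config.cytokine_noise_sd))
                )
                below = conc < config.lod_pg_per_ml
                panel_rows.append({
                    "analyte": spec.name,
                    "species": sp,
                    "gene_symbol": gene,
                    "sample_id": f"{sp[:2]}_{spec.name}_{group}_{m + 1}",
                    "group": group,
                    "concentration_pg_per_ml": 0.0 if below else conc,
                    "below_lod": below,
                    "extract_volume_ml": config.extract_volume_ml,
                    "tumour_mass_g": config.tumour_mass_g
                    * float(np.exp(rng.normal(0.0, 0.1))),
                    "lod_pg_per_ml": config.lod_pg_per_ml,
                })
        truth_rows.append({
            "analyte": spec.name,
            "species": sp,
            "gene_symbol": gene,
            "rna_fold": rna_fold,
            "gamma": spec.gamma,
            "protein_fold": protein_fold,
            "post_transcriptional": spec.gamma > 1.0,
        })
    panel = pd.DataFrame(panel_rows)
    analyte_truth = pd.DataFrame(truth_rows)
    truth.analytes = analyte_truth
    return panel, analyte_truth


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------

def _measurement_days(study_days: int) -> np.ndarray:
    """Thrice-weekly calliper schedule: days 0, 2, 4 of every week."""
    days = [w * 7 + o for w in range(study_days // 7 + 1) for o in (0, 2, 4)]
    return np.array([d for d in days if d <= study_days], dtype=float)


def _relative_volume(g: GrowthModel, group: str, t: np.ndarray) -> np.ndarray:
    if group == "untreated":
        return np.exp(g.growth_rate * t)
    f, d = g.regression_fraction, g.regression_days
    rel = np.where(
        t <= d,
        f ** (t / d),
        f * np.exp(g.regrowth_rate * (t - d)),
    )
    return rel


def generate_growth_curves(
    config: SynthConfig, truth: SynthTruth | None = None
) -> tuple[pd.DataFrame, SynthTruth]:
    """Per-mouse calliper axis pairs on a thrice-weekly schedule.

    Volumes follow the piecewise model times lognormal noise; axes are back-
    computed from volume at a fixed aspect ratio.  Truth records the analytic
    crossing time and the crossing of the linearly interpolated noise-free
    sampled curve (what a delay read off discrete measurement days gives).
    """
    g = config.growth
    rng = substream(config.seed, "growth")
    days = _measurement_days(g.study_days)
    q = g.aspect_ratio
    v_start = 0.52 * (g.start_diameter_mm * q) ** 2 * g.start_diameter_mm
    rows = []
    for group in ("untreated", "treated"):
        rel = _relative_volume(g, group, days)
        for m in range(g.n_per_group):
            v0 = v_start * float(np.exp(rng.normal(0.0, g.v0_cv)))
            noise = np.exp(rng.normal(0.0, g.noise_sd, size=len(days))) if g.noise_sd > 0 else 1.0
            vols = v0 * rel * noise
            b = (vols / (0.52 * q * q)) ** (1.0 / 3.0)
            a = q * b
            for day, ai, bi in zip(days, a, b):
                rows.append({
                    "mouse_id": f"{group[:2]}{m + 1}",
                    "group": group,
                    "day": float(day),
                    "a_mm": float(ai),
                    "b_mm": float(bi),
                })
    records = pd.DataFrame(rows)

    # noise-free group-mean relative curves and their interpolated crossing
    rel_treated = _relative_volume(g, "treated", days)
    crossing = g.crossing_time
    measured = np.nan
    below = rel_treated < 1.0
    if below.any():
        imin = int(np.argmin(rel_treated))
        for i in range(imin, len(days) - 1):
            if rel_treated[i] < 1.0 <= rel_treated[i + 1]:
                t0, t1 = days[i], days[i + 1]
                y0, y1 = rel_treated[i], rel_treated[i + 1]
                measured = float(t0 + (t1 - t0) * (1.0 - y0) / (y1 - y0))
                break
    if truth is None:
        truth = SynthTruth({}, {}, {}, {}, [], {})
    truth.growth = pd.DataFrame({
        "day": days,
        "untreated": _relative_volume(g, "untreated", days),
        "treated": rel_treated,
    })
    truth.growth_crossing_time = float(crossing)
    truth.growth_expected_measured_delay = measured
    return records, truth


# ---------------------------------------------------------------------------
# Necrosis masks
# ---------------------------------------------------------------------------

def generate_necrosis_mask(
    config: SynthConfig, truth: SynthTruth | None = None
) -> tuple[np.ndarray, float]:
    """Binary necrosis mask with pixel fraction within tolerance of target.

    Random disks are stamped until the target is reached; overshoot beyond
    the tolerance is trimmed by clearing randomly chosen necrotic pixels, so
    the realised fraction lands within one pixel of the target.  The exact
    realised fraction is recorded as truth.
    """
    spec = config.necrosis
    if not 0.0 <= spec.target_fraction <= 1.0:
        raise ValueError("target fraction must be in [0, 1]")
    rng = substream(config.seed, "masks")
    h, w = spec.height, spec.width
    n_px = h * w
    mask = np.zeros((h, w), dtype=bool)
    target = spec.target_fraction
    if target >= 1.0:
        mask[:] = True
    elif target > 0.0:
        r_lo, r_hi = spec.blob_radius_px
        if r_hi < 1:
            raise ValueError("blob radius must be >= 1 pixel")
        yy, xx = np.ogrid[:h, :w]
        it = 0
        while mask.mean() < target:
            it += 1
            if it > spec.max_iter:
                raise RuntimeError(
                    f"necrosis target {target} not reached in {spec.max_iter} blobs"
                )
            cy, cx = rng.integers(0, h), rng.integers(0, w)
            r = int(rng.integers(r_lo, r_hi + 1))
            mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        excess = int(round((mask.mean() - target) * n_px))
        if excess > 0:
            on = np.flatnonzero(mask.ravel())
            drop = rng.choice(on, size=excess, replace=False)
            flat = mask.ravel()
            flat[drop] = False
            mask = flat.reshape(h, w)
    realised = float(mask.mean())
    if abs(realised - target) > spec.tolerance:
        raise RuntimeError(
            f"realised necrosis fraction {realised:.4f} misses target {target:.4f}"
        )
    if truth is not None:
        truth.necrosis_fraction = realised
    return mask, realised


def write_mask_png(mask: np.ndarray, path, um_per_pixel: float) -> None:
    """Write a mask as single-channel PNG (255 = necrotic) plus a sidecar
    key-value file recording the pixel size."""
    from PIL import Image

    img = Image.fromarray((mask.astype(np.uint8)) * 255, mode="L")
    img.save(path)
    with open(str(path) + ".meta", "w", encoding="utf-8") as fh:
        fh.write(f"um_per_pixel\t{um_per_pixel}\n")


def read_mask_png(path) -> np.ndarray:
    from PIL import Image

    arr = np.asarray(Image.open(path).convert("L"))
    return arr >= 128


__all__ = [
    "AnalyteSpec",
    "GrowthModel",
    "NecrosisMaskSpec",
    "SynthConfig",
    "SynthTruth",
    "TreatmentSet",
    "Universe",
    "generate_control_hybs",
    "generate_cytokine_panel",
    "generate_growth_curves",
    "generate_necrosis_mask",
    "generate_universe",
    "generate_xenograft_arrays",
    "read_mask_png",
    "substream",
    "write_mask_png",
    "CONTROL_CONFIGS",
]
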