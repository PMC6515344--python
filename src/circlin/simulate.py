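"""Synthetic cohort generator with planted circRNA effects and ground truth.

The generator emulates the statistical structure the analysis assumes
in a case/control muscle-biopsy cohort:

* per-gene baseline expression (log-normal) and a baseline circular
  share of that expression (Beta prior);
* negative-binomial junction-read counts for the back-splice and for
  2-4 linear junctions sharing its donor or acceptor site (the linear
  total split by fixed Dirichlet weights), scaled by per-sample library
  size;
* a planted effect in cases: for true-positive genes the
  circular-to-linear odds f/(1-f) are multiplied by
  ``theta**(1 - c + c*s_i)``, where ``s_i`` is a latent per-case
  severity in [0, 1] and ``c`` the severity coupling — since the
  circular-to-linear ratio *is* the odds, ``theta`` is the planted fold
  change on the ratio scale;
* clinical covariates driven by the same severity: an MRC muscle
  strength megascore that decreases with severity, and MIRS disease
  stages 2-5 assigned by severity quartile (stage 1 is unused, as
  adult-onset cohorts rarely contain it);
* qPCR Ct values consistent with the count model
  (Ct = intercept - log2(abundance) + noise) plus reference genes tied
  to a shared per-sample size factor, so reference-averaged dCt values
  are unbiased;
* splicing event percentages (exon exclusion) linear in severity, with
  the implied inclusion/exclusion band-intensity pair for round-trip
  testing of gel quantification.

All randomness flows from one seed; each emitted table draws from its
own derived substream, so tables are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from circlin.io import CT_COLUMNS, SPLICING_COLUMNS, JunctionCountTable, event_id_for

# substream labels (SeedSequence spawn keys)
_STREAM_COHORT = 0
_STREAM_CT = 1
_STREAM_SPLICING = 2


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Cohort sizes default to a 30-case / 29-control muscle-biopsy
    validation cohort. Library sizes default to 5-20 million reads —
    a deliberately desk-scale depth; deep ribo-depleted libraries run
    an order of magnitude higher, and the scale is recorded in the
    ground truth so downstream consumers know what was simulated.

    ``ratio_fold`` (theta) is the planted fold change on the
    circular-to-linear ratio scale in cases; ``severity_coupling`` (c)
    moves the per-case exponent from constant (c=0, every case gets the
    full fold) to fully severity-graded (c=1, the fold scales with the
    latent severity).
    """

    n_cases: int = 30
    n_controls: int = 29
    n_genes: int = 60
    n_true_positive: int = 5
    ratio_fold: float = 2.0
    dispersion: float = 0.2
    lib_size_range: tuple[int, int] = (5_000_000, 20_000_000)
    circ_fraction_alpha: float = 2.0
    circ_fraction_beta: float = 6.0
    severity_coupling: float = 0.5
    mrc_baseline: float = 130.0
    mrc_drop: float = 18.0
    mrc_noise_sd: float = 3.0
    expression_log_mean: float = np.log(50.0)
    expression_log_sd: float = 1.0
    ct_intercept: float = 34.0
    ct_noise_sd: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_genes", "n_true_positive"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_true_positive > self.n_genes:
            raise ValueError("n_true_positive > n_genes")
        if self.ratio_fold <= 0:
            raise ValueError("ratio_fold must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        lo, hi = self.lib_size_range
        if not (0 < lo <= hi):
            raise ValueError("lib_size_range bounds must be positive and ordered")
        if self.circ_fraction_alpha <= 0 or self.circ_fraction_beta <= 0:
            raise ValueError("Beta prior parameters must be positive")
        if not 0.0 <= self.severity_coupling <= 1.0:
            raise ValueError("severity_coupling must lie in [0, 1]")
        if self.mrc_drop < 0 or self.mrc_noise_sd < 0 or self.ct_noise_sd < 0:
            raise ValueError("noise/drop parameters must be non-negative")


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort, for recovery tests.

    Beyond the planted-gene set, per-case severity and per-gene
    baseline circular fractions, it carries the latent quantities
    needed to derive isoform abundances downstream (baseline
    expression, per-sample size factors) and a metadata dict noting
    the simulated library-size scale.
    """

    true_positive_ids: set[str]
    severity: pd.Series  # case sample -> s in [0, 1]
    per_gene_baseline_fraction: pd.Series  # gene -> f in (0, 1)
    baseline_expression: pd.Series  # gene -> e_g (reads per million)
    size_factors: pd.Series  # sample -> shared abundance scale
    config: SimulationConfig
    metadata: dict = field(default_factory=dict)

    def circular_fraction(self, gene: str, sample: str, is_case: bool) -> float:
        """Realized circular share f for one gene in one sample."""
        f = float(self.per_gene_baseline_fraction[gene])
        odds = f / (1.0 - f)
        if is_case and gene in self.true_positive_ids:
            c = self.config.severity_coupling
            s = float(self.severity[sample])
            odds *= self.config.ratio_fold ** (1.0 - c + c * s)
        return odds / (1.0 + odds)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu**2.

    Zero dispersion degenerates to Poisson; zero mean gives zero
    counts without touching the generator state shape.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i:04d}" for i in range(1, n + 1)]


def _sample_ids(n_cases: int, n_controls: int) -> tuple[list[str], list[str]]:
    cases = [f"case_{i:02d}" for i in range(1, n_cases + 1)]
    controls = [f"ctrl_{i:02d}" for i in range(1, n_controls + 1)]
    return cases, controls


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[JunctionCountTable, pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Simulate back-splice counts, linear junctions, metadata and truth.

    One back-splice event per gene, placed on a synthetic genome
    (chromosomes cycled, loci spaced); each gene carries 2-4 linear
    junctions that share the event's donor or acceptor site, with fixed
    Dirichlet usage weights so the "highest expressed linear junction"
    choice is non-trivial but stable across samples.

    Returns ``(back_splice_table, linear_junctions, metadata, truth)``;
    byte-identical for a fixed config.
    """
    rng = _rng(config.seed, _STREAM_COHORT)
    genes = _gene_ids(config.n_genes)
    cases, controls = _sample_ids(config.n_cases, config.n_controls)
    samples = cases + controls

    # --- latent per-gene structure -------------------------------------
    e_g = rng.lognormal(config.expression_log_mean, config.expression_log_sd, config.n_genes)
    f_g = rng.beta(config.circ_fraction_alpha, config.circ_fraction_beta, config.n_genes)
    f_g = np.clip(f_g, 1e-6, 1 - 1e-6)
    tp_ids = set(rng.choice(genes, size=config.n_true_positive, replace=False)) if genes else set()

    # event geometry: one locus per gene
    chroms = [f"chr{(i % 22) + 1}" for i in range(config.n_genes)]
    starts = np.array([100_000 + 10_000 * i for i in range(config.n_genes)])
    ends = starts + 2_000
    strands = np.where(rng.random(config.n_genes) < 0.5, "+", "-")

    # linear junction layout per gene: 2-4 junctions touching the
    # back-splice donor or acceptor, fixed Dirichlet usage weights
    n_lin = rng.integers(2, 5, size=config.n_genes)
    lin_layout: list[list[tuple[int, int]]] = []
    lin_weights: list[np.ndarray] = []
    for i in range(config.n_genes):
        donor, acceptor = (ends[i], starts[i]) if strands[i] == "+" else (starts[i], ends[i])
        juncs = []
        for j in range(int(n_lin[i])):
            if j % 2 == 0:  # shares the donor site, splices downstream
                juncs.append((int(donor), int(donor) + 500 * (j // 2 + 1)))
            else:  # shares the acceptor site, splices upstream
                juncs.append((int(acceptor) - 500 * (j // 2 + 1), int(acceptor)))
        lin_layout.append(juncs)
        lin_weights.append(rng.dirichlet(np.ones(int(n_lin[i]))))

    # --- per-sample latent structure -----------------------------------
    lo, hi = config.lib_size_range
    lib_sizes = np.exp(rng.uniform(np.log(lo), np.log(hi), len(samples))).astype(np.int64)
    severity = pd.Series(rng.uniform(0.0, 1.0, len(cases)), index=cases)

    truth = CohortTruth(
        true_positive_ids=tp_ids,
        severity=severity,
        per_gene_baseline_fraction=pd.Series(f_g, index=genes),
        baseline_expression=pd.Series(e_g, index=genes),
        size_factors=pd.Series(lib_sizes / 1e7, index=samples),
        config=config,
        metadata={"lib_size_range": list(config.lib_size_range),
                  "lib_scale_note": "desk-scale libraries (5-20M reads)"},
    )

    # --- counts ---------------------------------------------------------
    # realized circular share per (gene, sample): planted genes in cases
    # get their circular-to-linear odds multiplied by theta**(1-c+c*s)
    n_s = len(samples)
    odds = np.repeat((f_g / (1.0 - f_g))[:, None], n_s, axis=1) if config.n_genes else np.zeros((0, n_s))
    if cases and config.n_genes:
        c = config.severity_coupling
        expo = 1.0 - c + c * severity.to_numpy()
        tp_mask = np.array([g in tp_ids for g in genes], dtype=bool)
        odds[np.ix_(tp_mask, np.arange(len(cases)))] *= config.ratio_fold ** expo[None, :]
    frac = odds / (1.0 + odds)
    mu_total = e_g[:, None] * (lib_sizes[None, :] * 1e-6)
    bs_counts = _nb_draw(rng, mu_total * frac, config.dispersion)
    lin_totals = _nb_draw(rng, mu_total * (1.0 - frac), config.dispersion)

    sample_arr = np.array(samples, dtype=object)
    cols: dict[str, list[np.ndarray]] = {k: [] for k in
                                         ("chrom", "donor_pos", "acceptor_pos",
                                          "strand", "sample_id", "count")}
    for gi in range(config.n_genes):
        split = rng.multinomial(lin_totals[gi].astype(np.int64), lin_weights[gi])
        for j, (dpos, apos) in enumerate(lin_layout[gi]):
            cols["chrom"].append(np.full(n_s, chroms[gi], dtype=object))
            cols["donor_pos"].append(np.full(n_s, dpos))
            cols["acceptor_pos"].append(np.full(n_s, apos))
            cols["strand"].append(np.full(n_s, strands[gi], dtype=object))
            cols["sample_id"].append(sample_arr)
            cols["count"].append(split[:, j])
    if cols["chrom"]:
        lin_frame = {k: np.concatenate(v) for k, v in cols.items()}
    else:
        lin_frame = {k: np.array([]) for k in cols}

    events = pd.DataFrame(
        {
            "event_id": [event_id_for(c, s, e) for c, s, e in zip(chroms, starts, ends)],
            "chrom": chroms,
            "start": starts,
            "end": ends,
            "strand": strands,
            "gene_id": genes,
        }
    ).set_index("event_id")
    counts = pd.DataFrame(bs_counts, index=events.index, columns=samples, dtype=float)
    bs_table = JunctionCountTable(
        events=events,
        counts=counts,
        normalized=False,
        lib_sizes=pd.Series(lib_sizes, index=samples),
    )
    linear = pd.DataFrame(lin_frame)
    linear["donor_pos"] = linear["donor_pos"].astype(int)
    linear["acceptor_pos"] = linear["acceptor_pos"].astype(int)
    linear["count"] = linear["count"].astype(float)

    # --- clinical covariates -------------------------------------------
    mrc_case = (
        config.mrc_baseline
        - config.mrc_drop * severity.to_numpy()
        + rng.normal(0.0, config.mrc_noise_sd, len(cases))
    )
    mrc_case = np.clip(mrc_case, 0.0, config.mrc_baseline)
    mirs_case = np.minimum(3, (severity.to_numpy() * 4).astype(int)) + 2  # quartile -> 2..5
    metadata = pd.DataFrame(
        {
            "sample_id": samples,
            "group": ["case"] * len(cases) + ["control"] * len(controls),
            "mrc_megascore": np.concatenate(
                [mrc_case, np.full(len(controls), config.mrc_baseline)]
            ),
            "mirs_stage": np.concatenate(
                [mirs_case.astype(float), np.full(len(controls), np.nan)]
            ),
            "lib_size": lib_sizes,
        }
    )
    return bs_table, linear, metadata, truth


# default reference genes used by the qPCR arm: ubiquitously expressed
# housekeeping transcripts at distinct abundance tiers
DEFAULT_REFERENCE_LEVELS = {"RPL13": 200.0, "RPL23": 120.0, "UBC": 60.0}


def simulate_ct_matrix(
    config: SimulationConfig,
    truth: CohortTruth,
    targets: list[str],
    reference_genes: list[str] | None = None,
    ct_noise_sd: float | None = None,
) -> pd.DataFrame:
    """Simulate qPCR Cts for circular/linear isoforms plus references.

    ``Ct = intercept - log2(abundance) + N(0, sigma_ct)``. A target
    gene's circular abundance in a sample is
    ``size_factor * e_g * f`` and its linear abundance
    ``size_factor * e_g * (1 - f)``, with f the same (possibly
    effect-shifted) circular share as in the count model. Reference
    genes amplify at a fixed level times the shared per-sample size
    factor, so averaging their Cts removes the size factor from every
    dCt exactly.
    """
    if reference_genes is None:
        reference_genes = list(DEFAULT_REFERENCE_LEVELS)
    unknown = [t for t in targets if t not in truth.baseline_expression.index]
    if unknown:
        raise ValueError(f"unknown target gene id(s): {unknown}")
    sigma = config.ct_noise_sd if ct_noise_sd is None else float(ct_noise_sd)

    rng = _rng(config.seed, _STREAM_CT)
    samples = list(truth.size_factors.index)
    case_set = set(truth.severity.index)
    records: list[tuple] = []
    for gene in targets:
        e = float(truth.baseline_expression[gene])
        for sid in samples:
            sf = float(truth.size_factors[sid])
            f = truth.circular_fraction(gene, sid, sid in case_set)
            for isoform, abundance in (("circular", sf * e * f), ("linear", sf * e * (1 - f))):
                ct = config.ct_intercept - np.log2(abundance) + rng.normal(0.0, sigma)
                records.append((gene, isoform, sid, 1, ct))
    ref_levels = {g: DEFAULT_REFERENCE_LEVELS.get(g, 100.0) for g in reference_genes}
    for gene, level in ref_levels.items():
        for sid in samples:
            abundance = float(truth.size_factors[sid]) * level
            ct = config.ct_intercept - np.log2(abundance) + rng.normal(0.0, sigma)
            records.append((gene, "reference", sid, 1, ct))
    return pd.DataFrame(records, columns=CT_COLUMNS)


@dataclass(frozen=True)
class SplicingEventSpec:
    """One simulated alternative-splicing assay.

    ``baseline`` is the control-group percent exon exclusion;
    ``slope`` its change per unit severity in cases (negative for
    events where disease promotes inclusion); ``noise_sd`` the
    Gaussian scatter in percent.
    """

    name: str
    direction: str  # "exclusion" or "inclusion"
    baseline: float
    slope: float
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.direction not in ("exclusion", "inclusion"):
            raise ValueError(f"invalid splicing direction {self.direction!r}")
        if not 0.0 <= self.baseline <= 100.0:
            raise ValueError("baseline percentage outside [0, 100]")


#: splicing assays emulated by default: two exon-exclusion events that
#: rise with severity and one inclusion event whose exclusion falls
DEFAULT_SPLICING_EVENTS = (
    SplicingEventSpec("INSR_ex11", "exclusion", baseline=20.0, slope=40.0),
    SplicingEventSpec("CAPZB_ex8", "exclusion", baseline=15.0, slope=35.0),
    SplicingEventSpec("NFIX_ex11", "inclusion", baseline=70.0, slope=-40.0),
)


def simulate_splicing_table(
    config: SimulationConfig,
    truth: CohortTruth,
    events: tuple[SplicingEventSpec, ...] = DEFAULT_SPLICING_EVENTS,
) -> pd.DataFrame:
    """Simulate percent exon exclusion and the implied band intensities.

    Cases follow ``baseline + slope * severity + noise``; controls
    ``baseline + noise``; everything clipped to [0, 100]. Each record
    also carries an inclusion/exclusion band-intensity pair with an
    arbitrary total intensity consistent with the percentage, so gel
    quantification can be round-trip tested.
    """
    rng = _rng(config.seed, _STREAM_SPLICING)
    samples = list(truth.size_factors.index)
    case_set = set(truth.severity.index)
    records = []
    for spec in events:
        for sid in samples:
            s = float(truth.severity[sid]) if sid in case_set else 0.0
            pct = spec.baseline + spec.slope * s + rng.normal(0.0, spec.noise_sd)
            pct = float(np.clip(pct, 0.0, 100.0))
            total = float(rng.uniform(1_000.0, 5_000.0))
            excl = total * pct / 100.0
            records.append((spec.name, spec.direction, sid, total - excl, excl, pct))
    return pd.DataFrame(records, columns=SPLICING_COLUMNS)
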