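"""Synthetic cohort generator with known ground truth.

Every downstream stage of the pipeline (co-expression modules, upstream
regulator ranking, GSEA, stratification, survival, CNA calling, drug
synergy) is exercised against cohorts produced here, where the latent
structure is known exactly:

* expression: a gene x sample matrix in which each planted module follows
  a one-factor model ``x_ij = beta * a_j + eps_ij`` with its own latent
  activity ``a`` (standard normal across samples, centered) and i.i.d.
  Gaussian residuals; the remaining background genes are pure noise.
  Module 1's latent factor plays the role of the driving regulator's
  activation state and is recorded as the truth activity.
* survival: exponential proportional hazards on the activity,
  ``h_j = baseline * exp(gamma * a_j)``, with independent censoring.
* copy number: per-sample piecewise-constant log-ratio tracks plus
  Gaussian probe noise; a designated segment carries a positive mean only
  in the amplified samples.
* dose-response: median-effect (Hill-type) single-agent curves
  ``fa/(1-fa) = (D/Dm)^m`` and combination points constructed at a known
  combination index.

A single global seed fans out to per-stage substreams
(``numpy.random.SeedSequence.spawn``) so each stage can be regenerated
independently and reproducibly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_survival",
    "generate_cna_profiles",
    "generate_dose_response",
    "generate_regulator_network",
]

# substream indices of the global seed sequence, one per generator stage
_STREAM_COHORT = 0
_STREAM_SURVIVAL = 1
_STREAM_CNA = 2
_STREAM_DOSE = 3
_STREAM_NETWORK = 4


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of a synthetic cohort.

    Defaults define the reference study conditions used throughout the
    test-suite: 60 samples, three planted modules of 50 genes within a
    1000-gene transcriptome (850 background genes), unit loading and
    residual sd 0.5, exponential survival tied to activity, a four-segment
    CNA track whose second segment is amplified in half the samples, and
    two median-effect drugs.
    """

    n_samples: int = 60
    n_genes: int = 1000
    module_sizes: tuple[int, ...] = (50, 50, 50)
    regulator_effect: float = 1.0     # loading beta of activity on module genes
    noise_sd: float = 0.5             # residual sd within planted modules
    survival_gamma: float = 1.0       # log-hazard coefficient on activity
    baseline_hazard: float = 0.1
    censor_rate: float = 0.2
    cna_segment_means: tuple[float, ...] = (0.0, 0.5, 0.0, -0.3)
    cna_probes_per_segment: int = 25
    cna_noise_sd: float = 0.1
    cna_neutral_mean: float = -0.1    # neutral-locus log-ratio in non-amplified samples
    amplified_segment: int = 1        # index into cna_segment_means
    amplified_fraction: float = 0.5
    drug_params: tuple[tuple[float, float], ...] = ((1.5, 1.0), (2.0, 0.5))
    true_ci: float = 1.0              # combination index used for combo points
    dose_noise_sd: float = 0.0        # measurement noise on viability
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if any(s < 1 for s in self.module_sizes):
            raise ConfigurationError("module_sizes entries must be >= 1")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigurationError(
                "module_sizes sum exceeds n_genes "
                f"({sum(self.module_sizes)} > {self.n_genes})"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be > 0")
        if not 0 <= self.censor_rate < 1:
            raise ConfigurationError("censor_rate must be in [0, 1)")
        if len(self.cna_segment_means) == 0:
            raise ConfigurationError("cna_segment_means must be nonempty")
        if self.cna_probes_per_segment < 1:
            raise ConfigurationError("cna_probes_per_segment must be >= 1")
        if self.cna_noise_sd < 0:
            raise ConfigurationError("cna_noise_sd must be >= 0")
        if not 0 <= self.amplified_segment < len(self.cna_segment_means):
            raise ConfigurationError("amplified_segment out of range")
        for m, dm in self.drug_params:
            if m <= 0 or dm <= 0:
                raise ConfigurationError("drug_params require m > 0 and Dm > 0")
        if self.true_ci <= 0:
            raise ConfigurationError("true_ci must be > 0")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def _rng(self, stream: int) -> np.random.Generator:
        child = np.random.SeedSequence(self.seed).spawn(stream + 1)[stream]
        return np.random.default_rng(child)


@dataclass
class SyntheticTruth:
    """Recorded ground truth of a generated cohort."""

    activity: pd.Series                 # per-sample latent activity (module 1)
    module_labels: pd.Series            # gene -> module id (0 = background)
    amplified_samples: frozenset[str] = frozenset()
    true_ci: float = 1.0


def _sample_ids(n: int) -> list[str]:
    return [f"S{i + 1:03d}" for i in range(n)]


def _gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:05d}" for i in range(n)]


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a gene x sample expression matrix with planted modules.

    Returns the expression DataFrame (genes in rows, samples in columns)
    and the :class:`SyntheticTruth` holding the centered activity of
    module 1 and the planted module labels (0 = background).
    """
    rng = config._rng(_STREAM_COHORT)
    genes = _gene_ids(config.n_genes)
    samples = _sample_ids(config.n_samples)

    values = np.empty((config.n_genes, config.n_samples))
    labels = np.zeros(config.n_genes, dtype=int)

    activities = []
    offset = 0
    for mod_idx, size in enumerate(config.module_sizes, start=1):
        a = rng.standard_normal(config.n_samples)
        a -= a.mean()  # activity has zero mean by construction
        eps = rng.normal(0.0, config.noise_sd, size=(size, config.n_samples))
        values[offset:offset + size] = config.regulator_effect * a + eps
        labels[offset:offset + size] = mod_idx
        activities.append(a)
        offset += size

    n_background = config.n_genes - offset
    if n_background:
        values[offset:] = rng.standard_normal((n_background, config.n_samples))

    expr = pd.DataFrame(values, index=genes, columns=samples)
    amplified = _amplified_samples(config, samples)
    activity = activities[0] if activities else np.zeros(config.n_samples)
    truth = SyntheticTruth(
        activity=pd.Series(activity, index=samples, name="activity"),
        module_labels=pd.Series(labels, index=genes, name="module"),
        amplified_samples=amplified,
        true_ci=config.true_ci,
    )
    return expr, truth


def _amplified_samples(config: SimulationConfig, samples: Sequence[str]) -> frozenset[str]:
    # deterministic given the seed; drawn from the CNA substream so the
    # cohort stage does not consume it
    rng = config._rng(_STREAM_CNA)
    n_amp = int(round(config.amplified_fraction * len(samples)))
    chosen = rng.choice(len(samples), size=n_amp, replace=False)
    return frozenset(samples[i] for i in sorted(chosen))


def generate_survival(
    activity: pd.Series, config: SimulationConfig
) -> pd.DataFrame:
    """Exponential proportional-hazards event times tied to activity.

    Hazard for sample j is ``baseline_hazard * exp(survival_gamma * a_j)``.
    Each record is independently censored with probability ``censor_rate``;
    a censored record's observed time is a uniform fraction of its latent
    event time, so censoring is independent of the event process.
    Returns a DataFrame with columns sample_id, time, event.
    """
    if config.baseline_hazard <= 0:
        raise ConfigurationError("baseline_hazard must be > 0")
    if len(activity) != config.n_samples:
        raise ConfigurationError(
            f"activity length {len(activity)} != n_samples {config.n_samples}"
        )
    rng = config._rng(_STREAM_SURVIVAL)
    a = np.asarray(activity, dtype=float)
    hazard = config.baseline_hazard * np.exp(config.survival_gamma * a)
    event_time = rng.exponential(1.0 / hazard)
    censored = rng.random(len(a)) < config.censor_rate
    frac = rng.random(len(a))
    time = np.where(censored, event_time * frac, event_time)
    # guard against an exactly-zero observed time
    time = np.maximum(time, np.finfo(float).tiny)
    return pd.DataFrame(
        {
            "sample_id": list(activity.index),
            "time": time,
            "event": (~censored).astype(int),
        }
    )


def generate_cna_profiles(
    config: SimulationConfig, truth: SyntheticTruth
) -> pd.DataFrame:
    """Piecewise-constant per-sample log-ratio probe tracks.

    All samples share the baseline segment means; the designated amplified
    segment keeps its (positive) configured mean only in
    ``truth.amplified_samples`` and takes ``cna_neutral_mean`` elsewhere
    (slightly negative by default: after tumor-vs-reference normalization
    a two-copy locus in an unstable genome sits just below zero, which
    keeps the strict >0 amplification label well defined). Probe-level
    Gaussian noise with sd ``cna_noise_sd`` is added independently per
    sample. Returns a DataFrame with columns probe_id, chrom, pos and one
    log-ratio column per sample.
    """
    if len(config.cna_segment_means) == 0:
        raise ConfigurationError("cna_segment_means must be nonempty")
    rng = config._rng(_STREAM_CNA)
    rng = np.random.default_rng(rng.integers(2**31))  # past the amp-sample draw
    ppseg = config.cna_probes_per_segment
    n_seg = len(config.cna_segment_means)
    n_probes = n_seg * ppseg
    samples = list(truth.activity.index)

    pos = np.arange(1, n_probes + 1) * 1000
    base = np.repeat(np.asarray(config.cna_segment_means, dtype=float), ppseg)
    amp_mask = np.zeros(n_probes, dtype=bool)
    amp_lo = config.amplified_segment * ppseg
    amp_mask[amp_lo:amp_lo + ppseg] = True

    out = pd.DataFrame(
        {
            "probe_id": [f"P{i + 1:05d}" for i in range(n_probes)],
            "chrom": "chr1",
            "pos": pos,
        }
    )
    for s in samples:
        mean = base.copy()
        if s not in truth.amplified_samples:
            mean[amp_mask] = config.cna_neutral_mean
        noise = rng.normal(0.0, config.cna_noise_sd, n_probes) if config.cna_noise_sd else 0.0
        out[s] = mean + noise
    return out


def amplified_locus(config: SimulationConfig) -> tuple[str, int]:
    """Genomic coordinate at the center of the designated amplified segment."""
    ppseg = config.cna_probes_per_segment
    center_probe = config.amplified_segment * ppseg + ppseg // 2
    return "chr1", int((center_probe + 1) * 1000)


def _median_effect_fa(dose: np.ndarray, m: float, dm: float) -> np.ndarray:
    ratio = (dose / dm) ** m
    return ratio / (1.0 + ratio)


def _median_effect_dx(fa: np.ndarray, m: float, dm: float) -> np.ndarray:
    return dm * (fa / (1.0 - fa)) ** (1.0 / m)


def generate_dose_response(
    config: SimulationConfig,
    n_doses: int = 8,
    combo_fa: Sequence[float] = (0.2, 0.35, 0.5, 0.65, 0.8),
) -> tuple[list[pd.DataFrame], pd.DataFrame, float]:
    """Single-agent curves and combination points at a known CI.

    Single-agent doses span ``Dm * 2**(-3..+4)`` (geometric, ``n_doses``
    points); viability is ``1 - fa`` under the median-effect model, with
    optional Gaussian measurement noise. Combination points are placed so
    that each drug contributes half of the configured combination index at
    the design fraction-affected: ``d_i = 0.5 * CI * Dx_i(fa)``, giving a
    true per-point CI of ``config.true_ci`` (1 = Loewe additivity).

    Returns ``(singles, combos, true_ci)`` where singles is one
    DataFrame(dose, viability) per configured drug and combos is a
    DataFrame(dose_a, dose_b, viability) over the two first drugs.
    """
    if any(f <= 0 or f >= 1 for f in combo_fa):
        raise InputError("combo design fa values must lie strictly in (0, 1)")
    if len(config.drug_params) < 2:
        raise ConfigurationError("drug_params must list at least two drugs")
    rng = config._rng(_STREAM_DOSE)

    singles = []
    for m, dm in config.drug_params:
        dose = dm * 2.0 ** np.arange(-3, -3 + n_doses)
        if np.any(dose <= 0):
            raise InputError("dose <= 0 in design")
        via = 1.0 - _median_effect_fa(dose, m, dm)
        if config.dose_noise_sd:
            via = np.clip(via + rng.normal(0, config.dose_noise_sd, via.shape), 1e-6, 1 - 1e-6)
        singles.append(pd.DataFrame({"dose": dose, "viability": via}))

    (ma, dma), (mb, dmb) = config.drug_params[0], config.drug_params[1]
    fa = np.asarray(combo_fa, dtype=float)
    dose_a = 0.5 * config.true_ci * _median_effect_dx(fa, ma, dma)
    dose_b = 0.5 * config.true_ci * _median_effect_dx(fa, mb, dmb)
    via = 1.0 - fa
    if config.dose_noise_sd:
        via = np.clip(via + rng.normal(0, config.dose_noise_sd, via.shape), 1e-6, 1 - 1e-6)
    combos = pd.DataFrame({"dose_a": dose_a, "dose_b": dose_b, "viability": via})
    return singles, combos, config.true_ci


def generate_regulator_network(
    truth: SyntheticTruth,
    config: SimulationConfig,
    n_decoys: int = 9,
    n_annotations: int = 5,
) -> tuple[pd.DataFrame, list[tuple[str, set[str]]]]:
    """Signed regulator->target network with one causal regulator.

    The planted regulator ``REG_TRUE`` activates every module-1 gene
    (edge sign +1, matching the positive loadings of the generative
    model). Each decoy regulator targets the same genes but with
    independently random +/-1 signs, so its expected direction agreement
    with the observed module is zero. Annotation gene sets partition the
    module genes into ``n_annotations`` blocks, emulating the
    function-term nodes a regulator is linked to.
    """
    rng = config._rng(_STREAM_NETWORK)
    module_genes = list(truth.module_labels.index[truth.module_labels == 1])
    if not module_genes:
        raise InputError("truth contains no module-1 genes")

    rows = [("REG_TRUE", g, 1) for g in module_genes]
    for d in range(n_decoys):
        signs = rng.choice([-1, 1], size=len(module_genes))
        rows.extend(
            (f"DECOY_{d + 1:02d}", g, int(s)) for g, s in zip(module_genes, signs)
        )
    network = pd.DataFrame(rows, columns=["regulator", "target", "sign"])

    blocks = np.array_split(np.asarray(module_genes), n_annotations)
    annotations = [
        (f"ANNOT_{i + 1:02d}", set(map(str, block)))
        for i, block in enumerate(blocks)
        if len(block)
    ]
    return network, annotations
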