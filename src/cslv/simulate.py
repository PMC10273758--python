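"""Synthetic SNP-array cohorts with known chromosomal-scale structure.

The generative model: every person carries a true length offset
``delta[p, s] ~ Normal(0, tau)`` (l2r units) for each partition segment
``s``, independent across segments and people. Disease risk follows a
logistic model on those offsets — linear terms plus optional pairwise
interactions — whose intercept is calibrated by root finding so the cohort
prevalence hits a target. Two observable representations are rendered:

* per-SNP l2r matrices: each SNP reports its segment's offset plus
  ``Normal(0, sigma)`` probe noise, at evenly spaced positions;
* SEG-style segment records: one record per (person, segment) whose
  absolute offset clears a reporting threshold — segments near diploid are
  left unrecorded, mimicking pipelines that only emit detected CNVs.

All randomness flows from a single seed through named ``SeedSequence``
streams, so every operation is fully deterministic and independent of call
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from cslv.features import SegmentPartition, partition_chromosomes
from cslv.genome import grch38_sizes
from cslv.io import (
    L2RMatrix,
    SegmentRecord,
    write_chrom_sizes,
    write_l2r,
    write_phenotypes,
    write_seg,
)

__all__ = [
    "RiskSpec",
    "SimulationConfig",
    "GroundTruth",
    "CalibrationError",
    "simulate_true_offsets",
    "calibrate_and_assign_labels",
    "render_l2r",
    "render_segment_records",
    "render_phenotypes",
    "subsample_exact",
    "write_simulation",
    "default_config",
    "strong_signal_risk_spec",
]

# SeedSequence stream keys, one per source of randomness
_STREAM_OFFSETS = 0
_STREAM_LABELS = 1
_STREAM_NOISE = 2
_STREAM_SUBSAMPLE = 3


class CalibrationError(RuntimeError):
    """Intercept calibration failed to bracket or converge."""


@dataclass(frozen=True)
class RiskSpec:
    """Logistic risk function on true segment offsets.

    ``linear`` maps a segment name (e.g. ``"3_q1"``) to its coefficient;
    ``interactions`` maps a pair of segment names to the coefficient of
    their product. Offsets are in l2r units (SD ``tau``), so a linear
    coefficient of 10 at tau = 0.1 contributes one log-odds SD. An empty
    spec is the null model: every person gets the baseline probability.
    """

    linear: Mapping[str, float] = field(default_factory=dict)
    interactions: Mapping[tuple[str, str], float] = field(default_factory=dict)
    intercept: float | None = None  # set by calibration

    @property
    def is_null(self) -> bool:
        return not self.linear and not self.interactions

    def segment_names(self) -> set[str]:
        names = set(self.linear)
        for a, b in self.interactions:
            names.update((a, b))
        return names

    def linear_predictor(self, offsets: pd.DataFrame) -> np.ndarray:
        """Risk score (without intercept) per person."""
        missing = self.segment_names() - set(offsets.columns)
        if missing:
            raise ValueError(f"risk spec references unknown segment(s): {sorted(missing)}")
        eta = np.zeros(len(offsets))
        for name, coef in self.linear.items():
            eta += coef * offsets[name].to_numpy()
        for (a, b), coef in self.interactions.items():
            eta += coef * offsets[a].to_numpy() * offsets[b].to_numpy()
        return eta


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Parameters
    ----------
    n_cases, n_controls : target class sizes for exact subsampling.
    chromosomes : (name, length-bp) pairs; defaults to the 22 GRCh38
        autosomes.
    snps_per_chromosome : probes per chromosome, evenly spaced.
    segments_per_chromosome : partition granularity k (4 = quarters).
    person_segment_sd : tau, SD of true per-person segment offsets (l2r).
    snp_noise_sd : sigma, SD of per-SNP probe noise (l2r).
    risk_spec : logistic risk function on the true offsets.
    target_prevalence : calibrated case probability, in (0, 1).
    seg_report_threshold : |offset| below which a SEG record is left
        unrecorded (the unreported-normal-region behaviour).
    seed : master seed; all streams derive from it.
    """

    n_cases: int = 1500
    n_controls: int = 4500
    chromosomes: tuple[tuple[str, int], ...] = tuple(grch38_sizes().items())
    snps_per_chromosome: int = 400
    segments_per_chromosome: int = 4
    person_segment_sd: float = 0.1
    snp_noise_sd: float = 0.2
    risk_spec: RiskSpec = field(default_factory=RiskSpec)
    target_prevalence: float = 0.25
    seg_report_threshold: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        if self.snps_per_chromosome < 1 or self.segments_per_chromosome < 1:
            raise ValueError("counts must be >= 1")
        if self.person_segment_sd < 0 or self.snp_noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0 < self.target_prevalence < 1:
            raise ValueError("target_prevalence must be in (0, 1)")
        if self.seg_report_threshold < 0:
            raise ValueError("seg_report_threshold must be >= 0")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be > 0")

    @property
    def sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def partition(self) -> SegmentPartition:
        return partition_chromosomes(
            self.sizes, k=self.segments_per_chromosome, include_x=True
        )

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


@dataclass
class GroundTruth:
    """Simulated cohort with its latent state.

    ``offsets`` is persons x segments (columns named like features);
    ``labels``/``probabilities`` are set by calibration.
    """

    offsets: pd.DataFrame
    config: SimulationConfig
    partition: SegmentPartition
    labels: np.ndarray | None = None
    probabilities: np.ndarray | None = None
    intercept: float | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.offsets.index)

    @property
    def n_persons(self) -> int:
        return len(self.offsets)

    def require_labels(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("labels not assigned; run calibrate_and_assign_labels first")
        return self.labels


def simulate_true_offsets(
    config: SimulationConfig, n_persons: int | None = None
) -> GroundTruth:
    """Draw true per-person segment offsets ``delta ~ Normal(0, tau)``.

    ``n_persons`` defaults to ``n_cases + n_controls``; draw a larger pool
    when exact class sizes will be subsampled afterwards.
    """
    if n_persons is None:
        n_persons = config.n_cases + config.n_controls
    if n_persons < 1:
        raise ValueError("n_persons must be >= 1")
    partition = config.partition()
    rng = config.rng(_STREAM_OFFSETS)
    values = rng.normal(0.0, config.person_segment_sd, size=(n_persons, len(partition)))
    ids = [f"S{i:06d}" for i in range(n_persons)]
    offsets = pd.DataFrame(values, index=pd.Index(ids, name="sample_id"),
                           columns=partition.feature_names)
    return GroundTruth(offsets=offsets, config=config, partition=partition)


def calibrate_intercept(eta: np.ndarray, target_prevalence: float, tol: float = 1e-6) -> float:
    """Intercept c such that mean(logistic(c + eta)) hits the target.

    The mean predicted probability is strictly increasing in c, so the root
    is found with Brent's method on an expanding bracket.
    """
    if not 0 < target_prevalence < 1:
        raise CalibrationError("target prevalence must be in (0, 1)")
    base = float(logit(target_prevalence))
    if np.allclose(eta, 0.0):
        return base

    def excess(c: float) -> float:
        return float(np.mean(expit(c + eta))) - target_prevalence

    spread = float(np.max(np.abs(eta))) + 1.0
    lo, hi = base - spread, base + spread
    for _ in range(60):
        if excess(lo) <= 0 <= excess(hi):
            break
        spread *= 2
        lo, hi = base - spread, base + spread
    else:
        raise CalibrationError("failed to bracket the intercept")
    root = float(brentq(excess, lo, hi, xtol=1e-12, rtol=8.9e-16))
    if abs(excess(root)) > tol:
        raise CalibrationError(f"calibration residual {excess(root):.2e} exceeds {tol}")
    return root


def calibrate_and_assign_labels(
    truth: GroundTruth,
    risk_spec: RiskSpec | None = None,
    target_prevalence: float | None = None,
) -> GroundTruth:
    """Calibrate the logistic intercept and draw Bernoulli labels.

    Returns a new GroundTruth with ``labels``, ``probabilities`` and
    ``intercept`` set; the input is not modified.
    """
    spec = risk_spec if risk_spec is not None else truth.config.risk_spec
    prevalence = (
        target_prevalence if target_prevalence is not None else truth.config.target_prevalence
    )
    eta = spec.linear_predictor(truth.offsets)
    intercept = calibrate_intercept(eta, prevalence)
    probabilities = expit(intercept + eta)
    rng = truth.config.rng(_STREAM_LABELS)
    labels = (rng.random(truth.n_persons) < probabilities).astype(np.int8)
    return GroundTruth(
        offsets=truth.offsets,
        config=truth.config,
        partition=truth.partition,
        labels=labels,
        probabilities=probabilities,
        intercept=intercept,
    )


def _snp_layout(truth: GroundTruth, chromosome: str) -> tuple[np.ndarray, np.ndarray]:
    """Evenly spaced 1-based SNP positions and their span indices (0..k-1)."""
    spans = truth.partition.spans_for(chromosome)
    length = spans[-1].end
    m = truth.config.snps_per_chromosome
    positions = 1 + (np.arange(m, dtype=np.int64) * length) // m
    positions = np.unique(positions)  # guards degenerate length < m layouts
    ends = np.array([s.end for s in spans])
    segment_idx = np.searchsorted(ends, positions - 1, side="right")
    return positions, segment_idx


def render_l2r(truth: GroundTruth) -> dict[str, L2RMatrix]:
    """Render per-chromosome l2r matrices: segment offset + probe noise."""
    truth.require_labels()
    rng = truth.config.rng(_STREAM_NOISE)
    out: dict[str, L2RMatrix] = {}
    col = 0
    for chrom in truth.partition.chromosomes:
        positions, segment_idx = _snp_layout(truth, chrom)
        k = len(truth.partition.spans_for(chrom))
        # offsets for this chromosome's spans: (persons, k)
        block = truth.offsets.iloc[:, col : col + k].to_numpy()
        col += k
        signal = block[:, segment_idx].T  # (n_snps, persons)
        noise = rng.normal(0.0, truth.config.snp_noise_sd, size=signal.shape)
        out[chrom] = L2RMatrix(chrom, positions, truth.sample_ids, signal + noise)
    return out


def render_segment_records(truth: GroundTruth) -> list[SegmentRecord]:
    """SEG-style records for segments whose |offset| clears the threshold.

    Near-diploid segments (|offset| below ``seg_report_threshold``) are
    simply not recorded — downstream consumers must treat the gaps as
    diploid, exactly as with masked CNV releases.
    """
    truth.require_labels()
    threshold = truth.config.seg_report_threshold
    records: list[SegmentRecord] = []
    probes: dict[str, np.ndarray] = {}
    for chrom in truth.partition.chromosomes:
        _, segment_idx = _snp_layout(truth, chrom)
        probes[chrom] = np.bincount(segment_idx, minlength=len(truth.partition.spans_for(chrom)))
    offsets = truth.offsets.to_numpy()
    for p, sample in enumerate(truth.sample_ids):
        for j, span in enumerate(truth.partition.spans):
            delta = offsets[p, j]
            if abs(delta) < threshold:
                continue
            records.append(
                SegmentRecord(
                    sample_id=sample,
                    chromosome=span.chromosome,
                    start=span.start + 1,
                    end=span.end,
                    num_probes=int(probes[span.chromosome][span.segment]),
                    segment_mean=float(delta),
                )
            )
    return records


def render_phenotypes(truth: GroundTruth, style: str = "ukb") -> pd.DataFrame:
    """Phenotype table consistent with the drawn labels.

    ``style="ukb"``: all women; cases carry both the self-report and the
    registry breast-cancer flag, controls carry no cancer flag.
    ``style="tcga"``: all women with a cancer diagnosis; cases have breast
    cancer, controls another cancer type.
    """
    labels = truth.require_labels()
    if style == "ukb":
        frame = pd.DataFrame({
            "sample_id": truth.sample_ids,
            "sex": "F",
            "self_report_cancer": labels.astype(bool),
            "registry_cancer": labels.astype(bool),
            "cancer_type": np.where(labels == 1, "breast", ""),
        })
    elif style == "tcga":
        frame = pd.DataFrame({
            "sample_id": truth.sample_ids,
            "sex": "F",
            "self_report_cancer": True,
            "registry_cancer": True,
            "cancer_type": np.where(labels == 1, "breast", "other"),
        })
    else:
        raise ValueError(f"unknown phenotype style {style!r}")
    return frame


def subsample_exact(truth: GroundTruth, n_cases: int | None = None,
                    n_controls: int | None = None) -> GroundTruth:
    """Subsample to exact class sizes (defaults from the config), seeded."""
    labels = truth.require_labels()
    n_cases = n_cases if n_cases is not None else truth.config.n_cases
    n_controls = n_controls if n_controls is not None else truth.config.n_controls
    case_idx = np.flatnonzero(labels == 1)
    control_idx = np.flatnonzero(labels == 0)
    if len(case_idx) < n_cases or len(control_idx) < n_controls:
        raise ValueError(
            f"pool has {len(case_idx)} cases / {len(control_idx)} controls; "
            f"requested {n_cases}/{n_controls} — simulate a larger pool"
        )
    rng = truth.config.rng(_STREAM_SUBSAMPLE)
    keep = np.sort(np.concatenate([
        rng.choice(case_idx, size=n_cases, replace=False),
        rng.choice(control_idx, size=n_controls, replace=False),
    ]))
    return GroundTruth(
        offsets=truth.offsets.iloc[keep],
        config=truth.config,
        partition=truth.partition,
        labels=labels[keep],
        probabilities=None if truth.probabilities is None else truth.probabilities[keep],
        intercept=truth.intercept,
    )


def write_simulation(truth: GroundTruth, outdir: str | Path, style: str = "ukb") -> None:
    """Write a rendered cohort to disk in all pipeline input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrices = render_l2r(truth)
    for chrom, matrix in matrices.items():
        write_l2r(
            matrix,
            outdir / f"chr{chrom}.l2r.txt",
            outdir / "samples.txt",
            outdir / f"chr{chrom}.positions.txt",
        )
    write_seg(render_segment_records(truth), outdir / "segments.seg")
    write_phenotypes(render_phenotypes(truth, style=style), outdir / "phenotypes.tsv")
    write_chrom_sizes(truth.config.sizes, outdir / "chrom.sizes")
    labels = pd.DataFrame({"sample_id": truth.sample_ids, "label": truth.require_labels()})
    labels.to_csv(outdir / "labels.tsv", sep="\t", index=False)
    truth.offsets.to_csv(outdir / "true_offsets.tsv", sep="\t", float_format="%.12g")


def strong_signal_risk_spec() -> RiskSpec:
    """A distributed, partly nonlinear risk function over quarter segments.

    Sixteen linear terms (coefficient +/-10, one log-odds SD each at
    tau = 0.1) spread over chromosomes 1-16, plus four pairwise
    interactions (coefficient +/-50) on chromosomes 17-22. No single
    segment dominates the signal, mirroring a trait driven by many small
    chromosomal-scale effects.
    """
    linear = {f"{c}_q{(c - 1) % 4}": (10.0 if c % 2 else -10.0) for c in range(1, 17)}
    interactions = {
        ("17_q1", "18_q2"): 50.0,
        ("19_q3", "20_q0"): 50.0,
        ("21_q1", "22_q2"): -50.0,
        ("17_q3", "21_q3"): -50.0,
    }
    return RiskSpec(linear=linear, interactions=interactions)


def default_config(
    signal: str = "strong",
    n_cases: int = 1500,
    n_controls: int = 4500,
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """Named study conditions: ``signal="strong"`` or ``"null"``.

    The strong condition uses :func:`strong_signal_risk_spec`; the null
    condition has an empty risk function (labels independent of genotype).
    """
    if signal == "strong":
        spec = strong_signal_risk_spec()
    elif signal == "null":
        spec = RiskSpec()
    else:
        raise ValueError(f"unknown signal condition {signal!r}")
    return SimulationConfig(
        n_cases=n_cases,
        n_controls=n_controls,
        risk_spec=spec,
        seed=seed,
        **overrides,
    )
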