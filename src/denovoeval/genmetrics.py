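"""Batch metrics, recovery/analogue statistics and the run tracker.

These are the quantities tracked while a SMILES generator trains or
samples: validity / uniqueness / novelty per batch, the probability of
recovering known active vs inactive reference molecules (and the resulting
active bias and its fold change over a baseline generator), fingerprint
analogue coverage of a reference set, and a per-interval time series of all
of the above plus the diversity metrics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from denovoeval.diversity import (
    SCAFFOLD_RADIUS,
    SphereConfig,
    internal_diversity,
    scaffold_metrics,
    sediv,
)
from denovoeval.fingerprints import (
    DEFAULT_FP_CONFIG,
    FingerprintConfig,
    fingerprint_matrix,
    snn_profile,
)
from denovoeval.standardize import bemis_murcko_scaffold, canonicalize

__all__ = [
    "BatchMetrics",
    "batch_metrics",
    "RecoveryReport",
    "recovery_probability",
    "AnalogueCoverage",
    "analogue_coverage",
    "MetricReport",
    "track_run",
]

#: Analogue definition: fingerprint Tanimoto similarity >= this (inclusive).
ANALOGUE_THRESHOLD = 0.4


@dataclass(frozen=True)
class BatchMetrics:
    """Validity, uniqueness and novelty of one generated batch.

    validity = valid / total; uniqueness = unique canonical strings among
    valid; novelty = unique canonical strings absent from the training set,
    over unique.  A fraction is None when its denominator is zero.
    """

    n_total: int
    n_valid: int
    n_unique: int
    n_novel: int

    @property
    def validity(self) -> float | None:
        return self.n_valid / self.n_total if self.n_total else None

    @property
    def uniqueness(self) -> float | None:
        return self.n_unique / self.n_valid if self.n_valid else None

    @property
    def novelty(self) -> float | None:
        return self.n_novel / self.n_unique if self.n_unique else None


def batch_metrics(batch: Sequence[str], train_canon: set[str]) -> BatchMetrics:
    """Compute validity/uniqueness/novelty for a batch of raw SMILES.

    ``train_canon`` must already be in this package's canonical dialect
    (see :func:`denovoeval.standardize.canonicalize`).
    """
    if len(batch) == 0:
        raise ValueError("empty batch")
    canon = [canonicalize(s) for s in batch]
    valid = [c for c in canon if c is not None]
    unique = list(dict.fromkeys(valid))
    novel = [c for c in unique if c not in train_canon]
    return BatchMetrics(
        n_total=len(batch),
        n_valid=len(valid),
        n_unique=len(unique),
        n_novel=len(novel),
    )


@dataclass
class RecoveryReport:
    """Probability of recovering known actives/inactives, and active bias.

    Per-sample probabilities are fractions of the valid-and-unique
    molecules of each sample whose canonical SMILES exactly matches a
    reference molecule.  ``bias`` is mean P(active) / mean P(inactive);
    ``fold_change`` is bias relative to a baseline (typically the
    unoptimized generator), absent without one.  Probabilities are stored
    unrounded; display scaling (x 1e-6) is left to serialization.
    """

    p_active: list[float]
    p_inactive: list[float]
    bias: float
    fold_change: float | None = None
    infinite_bias: bool = False

    @property
    def p_active_mean(self) -> float:
        return float(np.mean(self.p_active))

    @property
    def p_active_sd(self) -> float:
        return float(np.std(self.p_active, ddof=1)) if len(self.p_active) > 1 else 0.0

    @property
    def p_inactive_mean(self) -> float:
        return float(np.mean(self.p_inactive))

    @property
    def p_inactive_sd(self) -> float:
        return float(np.std(self.p_inactive, ddof=1)) if len(self.p_inactive) > 1 else 0.0

    @classmethod
    def from_probabilities(
        cls,
        p_active: float | Sequence[float],
        p_inactive: float | Sequence[float],
        baseline: "RecoveryReport | None" = None,
    ) -> "RecoveryReport":
        """Build a report directly from recovery probabilities.

        Useful for bias/fold-change arithmetic on probabilities measured
        elsewhere (e.g. published tables).
        """
        pa = [float(p) for p in np.atleast_1d(p_active)]
        pi = [float(p) for p in np.atleast_1d(p_inactive)]
        mean_pi = float(np.mean(pi))
        infinite = mean_pi == 0.0 and float(np.mean(pa)) > 0.0
        bias = math.inf if infinite else (0.0 if mean_pi == 0.0 else float(np.mean(pa)) / mean_pi)
        fold = None
        if baseline is not None:
            fold = 0.0 if baseline.bias == 0 else bias / baseline.bias
        return cls(p_active=pa, p_inactive=pi, bias=bias, fold_change=fold, infinite_bias=infinite)


def recovery_probability(
    samples: Sequence[Sequence[str]],
    actives: set[str],
    inactives: set[str],
    baseline: RecoveryReport | None = None,
) -> RecoveryReport:
    """Recovery probabilities over independent generator samples.

    Each sample is a list of raw SMILES; probabilities are computed over
    its valid-and-unique molecules.  Reference sets must be canonicalized
    already.  A sample with zero valid-unique molecules is a caller error.
    """
    p_act: list[float] = []
    p_inact: list[float] = []
    for i, sample in enumerate(samples):
        canon = [canonicalize(s) for s in sample]
        vu = set(c for c in canon if c is not None)
        if not vu:
            raise ValueError(f"sample {i} has no valid-unique molecules")
        p_act.append(len(vu & actives) / len(vu))
        p_inact.append(len(vu & inactives) / len(vu))
    return RecoveryReport.from_probabilities(p_act, p_inact, baseline)


@dataclass(frozen=True)
class AnalogueCoverage:
    """Fraction of generated molecules that are analogues of some
    reference, and fraction of references with at least one analogue."""

    gen_fraction: float
    ref_fraction: float


def analogue_coverage(
    gen_fps: np.ndarray | Sequence[np.ndarray],
    ref_fps: np.ndarray | Sequence[np.ndarray],
    threshold: float = ANALOGUE_THRESHOLD,
) -> AnalogueCoverage:
    """Analogue statistics at an inclusive similarity threshold.

    A generated molecule is an analogue iff its maximum Tanimoto similarity
    to any reference is >= threshold; a reference is covered iff some
    generated molecule is its analogue.
    """
    gen = np.asarray(gen_fps, dtype=bool)
    ref = np.asarray(ref_fps, dtype=bool)
    if gen.ndim == 1:
        gen = gen[None, :]
    if ref.ndim == 1:
        ref = ref[None, :]
    if gen.shape[0] == 0 or ref.shape[0] == 0:
        raise ValueError("both fingerprint sets must be non-empty")
    from denovoeval.fingerprints import tanimoto_matrix

    sims = tanimoto_matrix(gen, ref)
    gen_is_analogue = sims.max(axis=1) >= threshold
    ref_covered = sims.max(axis=0) >= threshold
    return AnalogueCoverage(
        gen_fraction=float(gen_is_analogue.mean()),
        ref_fraction=float(ref_covered.mean()),
    )


@dataclass
class MetricReport:
    """Named metric values for one interval/sample, JSON-serializable."""

    label: str
    metrics: dict[str, float | None]
    sizes: dict[str, int] = field(default_factory=dict)
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps(
            {"label": self.label, "metrics": self.metrics, "sizes": self.sizes, "seed": self.seed}
        )

    @classmethod
    def from_json(cls, text: str) -> "MetricReport":
        d = json.loads(text)
        return cls(label=d["label"], metrics=d["metrics"], sizes=d["sizes"], seed=d["seed"])


def reports_to_dataframe(reports: Sequence[MetricReport]) -> pd.DataFrame:
    rows = [{"label": r.label, **r.metrics} for r in reports]
    return pd.DataFrame(rows)


def _interval_report(
    label: str,
    molecules: list[str],
    train_canon: set[str],
    ref_fps: np.ndarray | None,
    sphere_config: SphereConfig,
    fp_config: FingerprintConfig,
) -> MetricReport:
    bm = batch_metrics(molecules, train_canon)
    canon_unique = list(dict.fromkeys(c for c in (canonicalize(s) for s in molecules) if c is not None))
    metrics: dict[str, float | None] = {
        "validity": bm.validity,
        "uniqueness": bm.uniqueness,
        "novelty": bm.novelty,
    }
    sizes = {"n_total": bm.n_total, "n_valid": bm.n_valid, "n_unique": bm.n_unique}
    if canon_unique:
        # Diversity metrics on the valid-unique set, @k-subsampled for cost.
        F = None
        if sphere_config.subsample_k is not None and len(canon_unique) > sphere_config.subsample_k:
            rng = np.random.default_rng(sphere_config.seed)
            idx = rng.choice(len(canon_unique), size=sphere_config.subsample_k, replace=False)
            eval_smiles = [canon_unique[i] for i in sorted(idx)]
        else:
            eval_smiles = canon_unique
        F = fingerprint_matrix(eval_smiles, fp_config)
        sed = sediv(F, SphereConfig(radius=sphere_config.radius, subsample_k=None))
        metrics["sediv"] = sed.value
        metrics["intdiv"] = internal_diversity(F)
        scaffolds = [bemis_murcko_scaffold(s) for s in eval_smiles]
        sm = scaffold_metrics(
            scaffolds, SphereConfig(radius=SCAFFOLD_RADIUS, subsample_k=None), fp_config
        )
        metrics["scaffold_uniqueness"] = sm.uniqueness
        metrics["scaffold_diversity"] = sm.diversity
        if ref_fps is not None:
            metrics["snn_to_refs"] = snn_profile(F, ref_fps).mean
        sizes["n_evaluated"] = len(eval_smiles)
    return MetricReport(label=label, metrics=metrics, sizes=sizes, seed=sphere_config.seed)


def track_run(
    batch_stream: Iterable[tuple[int, Sequence[str]]],
    train_canon: set[str],
    ref_fps: np.ndarray | None = None,
    every: int = 100,
    cumulative: bool = False,
    sphere_config: SphereConfig | None = None,
    fp_config: FingerprintConfig = DEFAULT_FP_CONFIG,
) -> Iterator[MetricReport]:
    """Per-interval metric time series over an ordered batch stream.

    ``batch_stream`` yields (step, SMILES batch) with strictly increasing
    steps starting at 1.  At every multiple of ``every``, a report is
    emitted for the molecules accumulated since the previous report (or
    since the start, with ``cumulative=True``): batch metrics plus SEDiv,
    internal diversity, scaffold metrics and, when reference fingerprints
    are given, mean single-nearest-neighbour similarity to them.
    """
    sphere_config = sphere_config or SphereConfig()
    acc: list[str] = []
    last_step: int | None = None
    for step, batch in batch_stream:
        if last_step is not None and step <= last_step:
            raise ValueError(f"unordered steps: {step} after {last_step}")
        last_step = step
        acc.extend(batch)
        if step % every == 0:
            yield _interval_report(
                f"step_{step}", acc, train_canon, ref_fps, sphere_config, fp_config
            )
            if not cumulative:
                acc = []
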