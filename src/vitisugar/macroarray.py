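"""cDNA macroarray quantification: presence calling, normalization, calls.

The experimental design this implements: each membrane carries every
gene dotted in triplicate, plus four reference genes (actin, EF1a, EF1g,
GAPDH) and salmon-sperm negative-control spots; each condition (organ or
berry developmental stage) is hybridized on two independent membranes,
so a gene/condition value is the mean of six spot-level measurements.

Pipeline, per membrane:

1. background subtraction, clipped at zero;
2. presence call — a gene is present only if its mean corrected
   intensity is strictly higher than the negative-control mean;
3. normalization — each spot divided by the mean over the four reference
   genes of their mean corrected intensities (absent genes are set to 0).

Across membranes, spot-level normalized values are averaged (absent
membranes contribute zeros).  A gene is flagged highly expressed in a
condition when its mean exceeds the mean over all genes in that
condition; the preferential-expression summary additionally reports the
most-expressed gene(s) per condition, genes whose level in one condition
is at least ``fold`` times their cross-condition mean, and genes induced
monotonically over an ordered developmental series.

The module is organised as a model/results pair:
``MacroarrayModel(rows, design).fit()`` returns an
:class:`ExpressionProfile` carrying the estimates and the call methods.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SpotRow

__all__ = [
    "DEFAULT_REFERENCE_GENES",
    "DEFAULT_NEGATIVE_CONTROLS",
    "correct_background",
    "presence_call",
    "MembraneExperiment",
    "normalize_membrane",
    "aggregate_replicates",
    "ExpressionValue",
    "ExpressionProfile",
    "CallTable",
    "PreferentialSummary",
    "MacroarrayModel",
    "call_high",
    "summarize_preferential",
    "northern_normalize",
]

DEFAULT_REFERENCE_GENES = frozenset({"actin", "EF1a", "EF1g", "GAPDH"})
DEFAULT_NEGATIVE_CONTROLS = frozenset({"salmon_sperm"})


def correct_background(raw_signal: float, background: float) -> float:
    """Background-subtracted intensity, clipped at zero."""
    if raw_signal < 0 or background < 0:
        raise ValueError("intensities must be non-negative")
    return max(raw_signal - background, 0.0)


def presence_call(gene_spots: Sequence[float], negatives: Sequence[float]) -> bool:
    """Present only if the gene's mean is strictly above the negative-control mean."""
    if len(gene_spots) == 0:
        raise ValueError("presence call needs at least one gene spot")
    if len(negatives) == 0:
        raise ValueError("presence call needs at least one negative-control spot")
    return float(np.mean(gene_spots)) > float(np.mean(negatives))


@dataclass
class MembraneExperiment:
    """All spots of one membrane (one condition per membrane)."""

    rows: list[SpotRow]
    reference_genes: frozenset[str] = DEFAULT_REFERENCE_GENES
    negative_controls: frozenset[str] = DEFAULT_NEGATIVE_CONTROLS

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("membrane has no spots")
        conditions = {r.condition for r in self.rows}
        if len(conditions) > 1:
            raise ValueError(f"one condition per membrane, got {sorted(conditions)}")
        membranes = {r.membrane_id for r in self.rows}
        if len(membranes) > 1:
            raise ValueError(f"rows from multiple membranes: {sorted(membranes)}")
        genes = {r.gene_id for r in self.rows}
        for ref in self.reference_genes:
            if ref not in genes:
                raise ValueError(f"reference gene {ref!r} has no spots on membrane "
                                 f"{self.membrane_id!r}")
        if not any(g in genes for g in self.negative_controls):
            raise ValueError(f"no negative-control spots on membrane {self.membrane_id!r}")

    @property
    def membrane_id(self) -> str:
        return self.rows[0].membrane_id

    @property
    def condition(self) -> str:
        return self.rows[0].condition

    def corrected(self, gene_id: str) -> list[float]:
        vals = [
            correct_background(r.raw_signal, r.background)
            for r in self.rows
            if r.gene_id == gene_id
        ]
        if not vals:
            raise KeyError(f"gene {gene_id!r} has no spots on membrane {self.membrane_id!r}")
        return vals

    def negative_mean(self) -> float:
        vals = [
            correct_background(r.raw_signal, r.background)
            for r in self.rows
            if r.gene_id in self.negative_controls
        ]
        return float(np.mean(vals))


def normalize_membrane(
    m: MembraneExperiment,
    reference_mass_factor: float = 1.0,
) -> dict[str, tuple[list[float], bool]]:
    """Per-gene spot-level relative expression on one membrane.

    Returns ``{gene: (normalized spot values, present)}`` for every
    non-reference, non-control gene.  The normalizer is the mean over
    the reference genes of their mean corrected intensities, divided by
    ``reference_mass_factor`` (1.0 reproduces the published convention
    of not correcting for the doubled reference spotting mass).  Genes
    failing the presence call get zeros.  An absent reference gene makes
    the whole membrane unusable.
    """
    if reference_mass_factor <= 0:
        raise ValueError("reference_mass_factor must be positive")
    neg_mean = m.negative_mean()
    ref_means = {}
    for ref in sorted(m.reference_genes):
        vals = m.corrected(ref)
        if not presence_call(vals, [neg_mean]):
            raise ValueError(
                f"reference gene {ref!r} absent on membrane {m.membrane_id!r}; "
                "membrane unusable"
            )
        ref_means[ref] = float(np.mean(vals))
    normalizer = float(np.mean(list(ref_means.values()))) / reference_mass_factor
    out: dict[str, tuple[list[float], bool]] = {}
    excluded = m.reference_genes | m.negative_controls
    for gene in sorted({r.gene_id for r in m.rows} - excluded):
        spots = m.corrected(gene)
        present = presence_call(spots, [neg_mean])
        if present:
            out[gene] = ([v / normalizer for v in spots], True)
        else:
            out[gene] = ([0.0] * len(spots), False)
    return out


@dataclass(frozen=True)
class ExpressionValue:
    """Mean relative expression of one gene in one condition."""

    gene_id: str
    condition: str
    mean: float
    sd: float
    n: int
    present: bool


def aggregate_replicates(
    gene_id: str,
    condition: str,
    per_membrane: Sequence[tuple[Sequence[float], bool]],
) -> ExpressionValue:
    """Pool spot-level normalized values across replicate membranes.

    ``per_membrane`` holds, for each membrane, the gene's normalized
    spot values and its presence flag there.  Absent membranes
    contribute their zeros; the gene is called present if it was present
    on at least one membrane.  A single membrane (n = 3 instead of 6)
    is accepted with a warning.
    """
    if not per_membrane:
        raise ValueError("need at least one replicate membrane")
    if len(per_membrane) == 1:
        warnings.warn(
            f"gene {gene_id!r} / condition {condition!r}: single membrane only "
            "(half the design's replicates)",
            stacklevel=2,
        )
    values = [v for spots, _ in per_membrane for v in spots]
    present = any(p for _, p in per_membrane)
    mean = float(np.mean(values)) if present else 0.0
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return ExpressionValue(gene_id, condition, mean, sd, len(values), present)


@dataclass
class CallTable:
    """Gene x condition flags: expression above the condition mean."""

    high: pd.DataFrame


@dataclass
class PreferentialSummary:
    """Condition-wise expression summary.

    ``above_mean``: genes above the all-gene mean per condition (the
    figure's listed genes); ``most_expressed``: argmax gene(s) per
    condition (the bold analogue); ``preferential``: gene x condition
    flags for level >= fold x the gene's cross-condition mean;
    ``induced``: genes rising monotonically over the ordered stage
    series with final >= fold x first (the underline analogue).
    """

    above_mean: dict[str, list[str]]
    most_expressed: dict[str, list[str]]
    preferential: pd.DataFrame
    induced: dict[str, bool]
    fold: float
    stage_order: tuple[str, ...] | None


def call_high(means: pd.DataFrame) -> CallTable:
    """Flag genes whose mean exceeds the all-gene mean of their condition."""
    if means.shape[0] < 2:
        raise ValueError("need at least 2 genes per condition")
    condition_means = means.mean(axis=0)
    return CallTable(high=means.gt(condition_means, axis=1))


def summarize_preferential(
    means: pd.DataFrame,
    fold: float = 2.0,
    stage_order: Sequence[str] | None = None,
) -> PreferentialSummary:
    """Quantified analogue of a preferential-expression summary figure."""
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    if means.shape[1] < 2:
        raise ValueError("need at least 2 conditions")
    high = call_high(means).high
    above = {c: [g for g in means.index if high.at[g, c]] for c in means.columns}
    most = {
        c: list(means.index[means[c] == means[c].max()]) for c in means.columns
    }
    overall = means.mean(axis=1)
    preferential = means.ge(fold * overall, axis=0) & (means > 0)
    induced: dict[str, bool] = {}
    if stage_order is not None:
        stages = list(stage_order)
        missing = [s for s in stages if s not in means.columns]
        if missing:
            raise ValueError(f"unknown stage(s): {', '.join(missing)}")
        for g in means.index:
            series = means.loc[g, stages].to_numpy(dtype=float)
            monotone = bool(np.all(np.diff(series) >= 0))
            induced[g] = bool(
                monotone and series[-1] >= fold * series[0] and series[-1] > 0
            )
    return PreferentialSummary(
        above_mean=above,
        most_expressed=most,
        preferential=preferential,
        induced=induced,
        fold=fold,
        stage_order=tuple(stage_order) if stage_order is not None else None,
    )


class ExpressionProfile:
    """Fitted gene x condition expression grid with its diagnostics.

    Attributes
    ----------
    means, sds, ns, present : DataFrame
        Gene x condition grids of the replicate mean, standard
        deviation, replicate count and presence flag.
    condition_means : Series
        Per-condition mean over all genes (the red-point threshold).
    """

    def __init__(self, values: dict[tuple[str, str], ExpressionValue]):
        genes = sorted({g for g, _ in values})
        conditions = sorted({c for _, c in values})
        for g in genes:
            for c in conditions:
                if (g, c) not in values:
                    raise ValueError(f"incomplete grid: missing ({g!r}, {c!r})")
        self.values = values
        self.means = pd.DataFrame(
            {c: [values[(g, c)].mean for g in genes] for c in conditions}, index=genes
        )
        self.sds = pd.DataFrame(
            {c: [values[(g, c)].sd for g in genes] for c in conditions}, index=genes
        )
        self.ns = pd.DataFrame(
            {c: [values[(g, c)].n for g in genes] for c in conditions}, index=genes
        )
        self.present = pd.DataFrame(
            {c: [values[(g, c)].present for g in genes] for c in conditions}, index=genes
        )
        self.condition_means = self.means.mean(axis=0)

    def call_high(self) -> CallTable:
        return call_high(self.means)

    def summarize_preferential(
        self, fold: float = 2.0, stage_order: Sequence[str] | None = None
    ) -> PreferentialSummary:
        return summarize_preferential(self.means, fold=fold, stage_order=stage_order)

    def summary(self) -> pd.DataFrame:
        """Long-format table: one row per gene/condition with calls."""
        high = self.call_high().high
        rows = []
        for (g, c), v in sorted(self.values.items()):
            rows.append(
                {
                    "gene_id": g,
                    "condition": c,
                    "mean": v.mean,
                    "sd": v.sd,
                    "n": v.n,
                    "present": v.present,
                    "high": bool(high.at[g, c]),
                }
            )
        return pd.DataFrame(rows)


class MacroarrayModel:
    """The macroarray quantification model over a set of spot rows.

    Parameters
    ----------
    rows : list of SpotRow
        Quantified spots from every membrane of the experiment.
    reference_genes, negative_controls : set of str
        Gene ids of the normalization references and negative controls.
    reference_mass_factor : float
        Divide reference intensities by this before normalizing (1.0 =
        no correction for the doubled reference spotting mass).
    """

    def __init__(
        self,
        rows: Sequence[SpotRow],
        reference_genes: Iterable[str] = DEFAULT_REFERENCE_GENES,
        negative_controls: Iterable[str] = DEFAULT_NEGATIVE_CONTROLS,
        reference_mass_factor: float = 1.0,
    ):
        self.reference_genes = frozenset(reference_genes)
        self.negative_controls = frozenset(negative_controls)
        self.reference_mass_factor = reference_mass_factor
        by_membrane: dict[str, list[SpotRow]] = {}
        for r in rows:
            by_membrane.setdefault(r.membrane_id, []).append(r)
        self.membranes = [
            MembraneExperiment(rs, self.reference_genes, self.negative_controls)
            for rs in by_membrane.values()
        ]

    def fit(self) -> ExpressionProfile:
        """Normalize every membrane and pool replicates per gene/condition."""
        normalized: dict[str, list[dict[str, tuple[list[float], bool]]]] = {}
        for m in self.membranes:
            normalized.setdefault(m.condition, []).append(
                normalize_membrane(m, self.reference_mass_factor)
            )
        values: dict[tuple[str, str], ExpressionValue] = {}
        for condition, membranes in normalized.items():
            genes = sorted(set().union(*(set(d) for d in membranes)))
            for g in genes:
                per = [d[g] for d in membranes if g in d]
                values[(g, condition)] = aggregate_replicates(g, condition, per)
        return ExpressionProfile(values)


def northern_normalize(signals: Mapping[str, float], reference: str) -> dict[str, float]:
    """Single-reference normalization used for RNA gel blots.

    Every signal is divided by the reference gene's signal; the
    reference maps to 1.0.
    """
    if reference not in signals:
        raise ValueError(f"reference gene {reference!r} has no signal")
    ref = float(signals[reference])
    if ref <= 0 or math.isnan(ref):
        raise ValueError(f"reference gene {reference!r} signal must be positive")
    return {g: float(v) / ref for g, v in signals.items()}
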