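"""Mutability-adjusted proportion of singletons (MAPS).

Rare singleton variants (allele count 1) are the footprint of recent,
possibly deleterious mutation; but the raw proportion of singletons in a
variant class confounds selection with local mutability, because highly
mutable trinucleotide contexts (e.g. CpG transitions) recur and are rarely
singletons.  MAPS removes the mutability component by calibrating the
expected singleton proportion per context on a neutral class (synonymous
coding variants) and reporting, for any class of interest,

    MAPS = (observed singletons - expected singletons) / n variants.

Positive MAPS means the class holds more singletons than its mutational
context composition predicts -- the signature of negative selection.

The calibration is exposed as a model/results pair:

    model = MapsModel(neutral_variants, rates)
    res = model.fit()            # MapsModelResults
    res.score_class(variants)    # -> MapsResult with bootstrap CI

Inference is fully nonparametric: percentile bootstrap CIs (resampling
variants with replacement) and paired-bootstrap one-sided p-values with the
(1 + k)/(n_iter + 1) finite-sample correction, so a p-value of exactly zero
is never reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genomic_model import VariantRecord
from .resampling import bootstrap_means, paired_exceedance_pvalue

logger = logging.getLogger(__name__)


class MutationRateTable:
    """Context-dependent mutation rates keyed by collapsed context (+ alt).

    Keys are the package's collapsed context strings ``"XYZ>A"``; an optional
    methylation level {0,1,2} refines CpG contexts when provided.
    """

    def __init__(self, rates: dict):
        # keys: "XYZ>A" or ("XYZ>A", methyl_level)
        self._rates = {}
        for k, mu in rates.items():
            if mu <= 0:
                raise ValueError(f"mutation rate for {k} must be positive")
            self._rates[k] = float(mu)

    def get(self, context: str, methyl_level: int | None = None) -> float:
        if methyl_level is not None and (context, methyl_level) in self._rates:
            return self._rates[(context, methyl_level)]
        if context not in self._rates:
            raise KeyError(f"no mutation rate for context {context}")
        return self._rates[context]

    def __contains__(self, context: str) -> bool:
        return context in self._rates

    def contexts(self) -> list[str]:
        return sorted(k for k in self._rates if isinstance(k, str))

    @classmethod
    def from_tsv(cls, path) -> "MutationRateTable":
        """Columns: context (triplet), alt, optional methyl_level, mu."""
        df = pd.read_csv(path, sep="\t")
        rates: dict = {}
        for row in df.itertuples(index=False):
            key = f"{row.context}>{row.alt}"
            if "methyl_level" in df.columns and not pd.isna(row.methyl_level):
                rates[(key, int(row.methyl_level))] = row.mu
            else:
                rates[key] = row.mu
        return cls(rates)

    def to_tsv(self, path) -> None:
        rows = []
        for k, mu in sorted(self._rates.items(), key=lambda kv: str(kv[0])):
            if isinstance(k, tuple):
                ctx, methyl = k
            else:
                ctx, methyl = k, ""
            triplet, alt = ctx.split(">")
            rows.append((triplet, alt, methyl, mu))
        pd.DataFrame(rows, columns=["context", "alt", "methyl_level", "mu"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class MapsResult:
    """MAPS score for one variant class, with its bootstrap interval."""

    label: str
    n_variants: int
    observed_singletons: int
    expected_singletons: float
    maps: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_variants": self.n_variants,
            "observed_singletons": self.observed_singletons,
            "expected_singletons": self.expected_singletons,
            "maps": self.maps,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_boot": self.n_boot,
        }


def _contexts_and_singletons(
    variants: list[VariantRecord],
) -> tuple[list[str], np.ndarray]:
    ctx = []
    sing = np.empty(len(variants), dtype=float)
    for i, v in enumerate(variants):
        if v.context is None:
            raise ValueError(
                f"variant {v.chrom}:{v.pos} has no context; annotate before MAPS"
            )
        ctx.append(v.context)
        sing[i] = 1.0 if v.is_singleton else 0.0
    return ctx, sing


class MapsModel:
    """Mutability calibration of singleton proportions on a neutral class.

    Parameters
    ----------
    neutral_variants
        The calibration class (synonymous coding variants in the source
        analysis), each with a populated collapsed mutation context.
    rates
        Context-dependent mutation rates covering every context present.
    use_methylation
        Refine contexts by methylation level where the variant and rate
        table both carry one (off by default).
    link
        ``"linear"`` (weighted least squares of per-context singleton
        proportion on the raw rate, the default) or ``"logit"``.
    """

    def __init__(
        self,
        neutral_variants: list[VariantRecord],
        rates: MutationRateTable,
        use_methylation: bool = False,
        link: str = "linear",
    ):
        if link not in ("linear", "logit"):
            raise ValueError("link must be 'linear' or 'logit'")
        if not neutral_variants:
            raise ValueError("no variants in calibration class")
        self.rates = rates
        self.use_methylation = use_methylation
        self.link = link
        ctx, sing = _contexts_and_singletons(neutral_variants)
        if use_methylation:
            keys = [
                (c, v.methylation_level) if v.methylation_level is not None else (c, None)
                for c, v in zip(ctx, neutral_variants)
            ]
        else:
            keys = [(c, None) for c in ctx]
        df = pd.DataFrame({"key": keys, "context": ctx, "singleton": sing})
        grouped = df.groupby("key", sort=True)
        self.training = pd.DataFrame(
            {
                "n": grouped["singleton"].size(),
                "singletons": grouped["singleton"].sum(),
            }
        )
        self.training["proportion"] = (
            self.training["singletons"] / self.training["n"]
        )
        missing = [
            k for (k, _m) in self.training.index if k not in rates
        ]
        if missing:
            raise KeyError(f"contexts missing from rate table: {sorted(set(missing))}")
        self.training["mu"] = [
            rates.get(k, m if use_methylation else None)
            for (k, m) in self.training.index
        ]

    def fit(self) -> "MapsModelResults":
        """Weighted regression of per-context singleton proportion on rate.

        Weights are per-context variant counts.  With a single distinct rate
        (or a single context) the model is saturated to the pooled
        proportion (intercept-only fit).
        """
        t = self.training
        y = t["proportion"].to_numpy()
        mu = t["mu"].to_numpy()
        w = t["n"].to_numpy(dtype=float)
        distinct_mu = np.unique(mu).size
        if self.link == "logit":
            # grouped binomial GLM with logit link, weighted by counts
            exog = sm.add_constant(mu) if distinct_mu > 1 else np.ones((len(y), 1))
            glm = sm.GLM(
                np.column_stack([t["singletons"], t["n"] - t["singletons"]]),
                exog,
                family=sm.families.Binomial(),
            ).fit()
            fitted = np.asarray(glm.predict(exog))
            params = np.asarray(glm.params)
        else:
            if distinct_mu > 1:
                exog = sm.add_constant(mu)
            else:
                exog = np.ones((len(y), 1))
            wls = sm.WLS(y, exog, weights=w).fit()
            fitted = np.asarray(wls.fittedvalues)
            params = np.asarray(wls.params)
        fitted = np.clip(fitted, 0.0, 1.0)
        phat = dict(zip(t.index, fitted))
        return MapsModelResults(self, params, phat)


class MapsModelResults:
    """Fitted MAPS calibration: per-context expected singleton proportions."""

    def __init__(self, model: MapsModel, params: np.ndarray, phat: dict):
        self.model = model
        self.params = params
        self._phat = phat

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def slope(self) -> float:
        return float(self.params[1]) if len(self.params) > 1 else 0.0

    def predict(self, context: str, methyl_level: int | None = None) -> float:
        """Expected singleton proportion for one context.

        Contexts seen in training use their fitted value; unseen contexts
        fall back to the regression line evaluated at the context's rate.
        """
        key = (context, methyl_level if self.model.use_methylation else None)
        if key in self._phat:
            return self._phat[key]
        if (context, None) in self._phat:
            return self._phat[(context, None)]
        mu = self.model.rates.get(
            context, methyl_level if self.model.use_methylation else None
        )
        if self.model.link == "logit":
            eta = self.intercept + self.slope * mu
            return float(np.clip(1.0 / (1.0 + np.exp(-eta)), 0.0, 1.0))
        return float(np.clip(self.intercept + self.slope * mu, 0.0, 1.0))

    def expected_per_variant(self, variants: list[VariantRecord]) -> np.ndarray:
        ctx, _ = _contexts_and_singletons(variants)
        return np.array(
            [
                self.predict(c, v.methylation_level)
                for c, v in zip(ctx, variants)
            ]
        )

    def score_class(
        self,
        variants: list[VariantRecord],
        label: str = "",
        n_boot: int = 0,
        percentiles: tuple[float, float] = (5.0, 95.0),
        seed: int | None = None,
    ) -> MapsResult:
        """MAPS score of a variant class, optionally with a bootstrap CI.

        The default percentile pair (5, 95) gives the 90% interval used for
        the headline score panels; pass (2.5, 97.5) for 95% intervals.
        """
        if not variants:
            raise ValueError(f"no variants in class {label!r}")
        _, sing = _contexts_and_singletons(variants)
        expected = self.expected_per_variant(variants)
        n = len(variants)
        score = (sing.sum() - expected.sum()) / n
        result = MapsResult(
            label=label,
            n_variants=n,
            observed_singletons=int(sing.sum()),
            expected_singletons=float(expected.sum()),
            maps=float(score),
        )
        if n_boot > 0:
            lo, hi = bootstrap_maps(
                variants, self, n_iter=n_boot, percentiles=percentiles, seed=seed
            )
            result.ci_low, result.ci_high, result.n_boot = lo, hi, n_boot
        return result

    def summary(self) -> str:
        t = self.model.training
        lines = [
            "MAPS calibration (weighted %s fit)" % self.model.link,
            f"  contexts: {len(t)}    variants: {int(t['n'].sum())}    "
            f"singletons: {int(t['singletons'].sum())}",
            f"  intercept: {self.intercept:.6g}    slope: {self.slope:.6g}",
            "",
            "  context         methyl      n  singletons  proportion        mu    fitted",
        ]
        for key, row in t.iterrows():
            ctx, methyl = key
            lines.append(
                f"  {ctx:<14}{str(methyl) if methyl is not None else '-':>7}"
                f"{int(row['n']):>8}{int(row['singletons']):>11}"
                f"{row['proportion']:>12.4f}{row['mu']:>10.4g}"
                f"{self._phat[key]:>10.4f}"
            )
        return "\n".join(lines)


def fit_calibration(
    neutral_variants: list[VariantRecord],
    rates: MutationRateTable,
    **kwargs,
) -> MapsModelResults:
    """Convenience wrapper: build and fit the calibration in one call."""
    return MapsModel(neutral_variants, rates, **kwargs).fit()


def maps_score(
    variants: list[VariantRecord],
    model: MapsModelResults,
    label: str = "",
    **kwargs,
) -> MapsResult:
    """MAPS score of a class under a fitted calibration (see ``score_class``)."""
    return model.score_class(variants, label=label, **kwargs)


def bootstrap_maps(
    variants: list[VariantRecord],
    model: MapsModelResults,
    n_iter: int = 10000,
    percentiles: tuple[float, float] = (5.0, 95.0),
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for a class's MAPS score.

    Resamples the n variants with replacement ``n_iter`` times and takes the
    requested percentiles of the recomputed scores.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    _, sing = _contexts_and_singletons(variants)
    expected = model.expected_per_variant(variants)
    values = sing - expected  # per-variant contribution; score = mean
    rng = np.random.default_rng(seed)
    scores = bootstrap_means(values, n_iter, rng)
    lo, hi = np.percentile(scores, percentiles)
    return float(lo), float(hi)


def maps_pvalue(
    class_a: list[VariantRecord],
    class_b: list[VariantRecord],
    model: MapsModelResults,
    n_iter: int = 10000,
    seed: int | None = None,
) -> float:
    """Paired-bootstrap one-sided p-value for "class a exceeds class b".

    Both classes are resampled with replacement in each iteration; the
    p-value is the corrected fraction of iterations where the experimental
    score fails to exceed the control score (exact ties counting half),
    p = (1 + k) / (n_iter + 1).
    """
    if not class_a or not class_b:
        raise ValueError("both classes must be non-empty")
    _, sing_a = _contexts_and_singletons(class_a)
    _, sing_b = _contexts_and_singletons(class_b)
    va = sing_a - model.expected_per_variant(class_a)
    vb = sing_b - model.expected_per_variant(class_b)
    rng = np.random.default_rng(seed)
    scores_a = bootstrap_means(va, n_iter, rng)
    scores_b = bootstrap_means(vb, n_iter, rng)
    return paired_exceedance_pvalue(scores_a, scores_b)


def match_by_context(
    target_class: list[VariantRecord],
    pool: list[VariantRecord],
    seed: int | None = None,
) -> list[VariantRecord]:
    """Sample a control class whose context histogram equals the target's.

    For each context the required number of variants is drawn from the pool;
    sampling is without replacement when the pool stratum is large enough,
    otherwise with replacement (logged).  Raises KeyError when a target
    context is absent from the pool.
    """
    if not target_class:
        return []
    rng = np.random.default_rng(seed)
    by_ctx: dict[str, list[VariantRecord]] = {}
    for v in pool:
        by_ctx.setdefault(v.context, []).append(v)
    need: dict[str, int] = {}
    for v in target_class:
        need[v.context] = need.get(v.context, 0) + 1
    missing = [c for c in need if c not in by_ctx]
    if missing:
        raise KeyError(f"contexts absent from pool: {sorted(missing)}")
    control: list[VariantRecord] = []
    for ctx, k in need.items():
        stratum = by_ctx[ctx]
        replace = k > len(stratum)
        if replace:
            logger.warning(
                "context %s: need %d, pool has %d; sampling with replacement",
                ctx,
                k,
                len(stratum),
            )
        idx = rng.choice(len(stratum), size=k, replace=replace)
        control.extend(stratum[i] for i in idx)
    return control
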