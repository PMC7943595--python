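"""Single-variant PheWAS and gene-burden association layer.

Case/control status is derived from dated diagnosis events: an individual is
a case for a phenotype code with events on >= 2 distinct dates (the default,
EHR-style rule), a control with no event for the code, and excluded with
exactly one dated event.  A one-encounter mode (``min_case_dates=1``)
mirrors datasets where repeat encounters are rare.

Each eligible variant x phenotype pair is tested with a covariate-adjusted
logistic regression (age, age^2, sex, PC1..PC10 by convention) under an
additive genotype coding, per ancestry stratum, and strata are combined by
inverse-variance-weighted (IVW) fixed-effect meta-analysis.  Eligibility
requires >= 5 total alternate alleles, <= 50% missing genotypes, and >= 20
cases.  Significance lines follow standard PheWAS practice: Bonferroni
alpha / (n_variants x n_phenotypes) and the plotted FDR line
fdr_level / n_phenotypes (a Benjamini-Hochberg step-up over observed
p-values is also provided for reporting).

Gene burdens collapse rare (MAF <= 0.1%) pLOF and predicted-deleterious
missense (REVEL >= 0.5) variants additively per gene.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ["age", "age2", "sex"] + [f"PC{i}" for i in range(1, 11)]


@dataclass
class AssociationResult:
    """Effect estimate for one variant/burden x phenotype pair."""

    test_id: str
    phenotype: str
    beta: float
    se: float
    p_value: float
    n_cases: int
    n_controls: int
    stratum: str = "all"
    converged: bool = True
    separation: bool = False

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci(self) -> tuple[float, float]:
        """95% Wald CI on the odds-ratio scale."""
        return (
            float(np.exp(self.beta - 1.96 * self.se)),
            float(np.exp(self.beta + 1.96 * self.se)),
        )

    @property
    def reliable(self) -> bool:
        """Usable for thresholding: converged without separation."""
        return self.converged and not self.separation

    def to_dict(self) -> dict:
        lo, hi = self.ci
        return {
            "test_id": self.test_id,
            "phenotype": self.phenotype,
            "beta": self.beta,
            "se": self.se,
            "odds_ratio": self.odds_ratio,
            "ci_low": lo,
            "ci_high": hi,
            "p_value": self.p_value,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "stratum": self.stratum,
            "converged": self.converged,
            "separation": self.separation,
        }

    def summary(self) -> str:
        lo, hi = self.ci
        return (
            f"{self.test_id} x {self.phenotype} [{self.stratum}]: "
            f"OR {self.odds_ratio:.3g} ({lo:.3g}-{hi:.3g}), "
            f"P = {self.p_value:.3g}, {self.n_cases} cases / "
            f"{self.n_controls} controls"
            + ("" if self.reliable else "  [unreliable fit]")
        )


def derive_case_control(
    events: pd.DataFrame,
    phenotype_code: str,
    individuals: pd.Index | list,
    min_case_dates: int = 2,
    control_exclusion_codes: set[str] | None = None,
) -> pd.Series:
    """Per-individual status {case, control, excluded} for one phenotype.

    ``events`` has columns individual, code, date; duplicate (code, date)
    pairs count once.  Individuals with >= ``min_case_dates`` distinct dates
    are cases; no event, controls; fewer dates than the case rule demands,
    excluded.  Controls carrying any code in ``control_exclusion_codes``
    (related phenotypes) are excluded too.
    """
    sub = events[events["code"].astype(str) == str(phenotype_code)]
    n_dates = sub.drop_duplicates(["individual", "date"]).groupby("individual").size()
    status = pd.Series("control", index=pd.Index(individuals, name="individual"))
    counted = n_dates.reindex(status.index).fillna(0).astype(int)
    status[counted >= min_case_dates] = "case"
    status[(counted > 0) & (counted < min_case_dates)] = "excluded"
    if control_exclusion_codes:
        excl_ind = events[
            events["code"].astype(str).isin({str(c) for c in control_exclusion_codes})
        ]["individual"].unique()
        mask = status.index.isin(excl_ind) & (status == "control")
        status[mask] = "excluded"
    return status


def eligibility_filters(
    dosages: pd.Series,
    statuses: pd.Series,
    min_alt_alleles: int = 5,
    max_missing_frac: float = 0.5,
    min_cases: int = 20,
) -> tuple[bool, list[str]]:
    """Pre-test eligibility with machine-readable failure reasons."""
    reasons: list[str] = []
    d = dosages.reindex(statuses.index)
    if float(d.sum(skipna=True)) < min_alt_alleles:
        reasons.append("min_alt_alleles")
    if d.isna().mean() > max_missing_frac:
        reasons.append("max_missing_frac")
    if int((statuses == "case").sum()) < min_cases:
        reasons.append("min_cases")
    return (not reasons), reasons


def _firth_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Firth-penalised logistic regression (Jeffreys-prior score correction).

    Returns (beta, cov).  Used as a fallback when rare carriers separate the
    outcome and plain ML diverges.
    """
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        XtW = X.T * w
        info = XtW @ X
        info_inv = np.linalg.inv(info)
        # hat-matrix diagonal of the weighted design
        h = np.einsum("ij,jk,ik->i", X * w[:, None], info_inv, X)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu)
    cov = np.linalg.inv((X.T * w) @ X)
    return beta, cov


def logistic_assoc(
    dosages: pd.Series,
    statuses: pd.Series,
    covariates: pd.DataFrame | None = None,
    test_id: str = "",
    phenotype: str = "",
    stratum: str = "all",
    firth: bool = False,
) -> AssociationResult:
    """Covariate-adjusted additive logistic association for one variant.

    Fits case ~ dosage + covariates by maximum likelihood and reports the
    Wald estimate for the dosage term.  Complete/quasi separation is
    detected and flagged on the result (never silently returned as a huge
    finite OR); with ``firth=True`` the Firth-penalised fit is used instead,
    which remains finite under separation.
    """
    keep = statuses.isin(["case", "control"])
    d = dosages.reindex(statuses.index)
    keep &= d.notna()
    y = (statuses[keep] == "case").astype(float).to_numpy()
    x = d[keep].to_numpy(dtype=float)
    n_cases = int(y.sum())
    n_controls = int(len(y) - y.sum())
    cols = [x]
    if covariates is not None:
        cov = covariates.reindex(statuses.index)[keep]
        if cov.isna().any().any():
            raise ValueError("missing covariate values")
        cols.append(cov.to_numpy(dtype=float))
    X = sm.add_constant(np.column_stack(cols))

    if firth:
        beta_vec, cov_mat = _firth_logit(X, y)
        beta, se = float(beta_vec[1]), float(np.sqrt(cov_mat[1, 1]))
        z = beta / se
        p = 2 * stats.norm.sf(abs(z))
        return AssociationResult(
            test_id, phenotype, beta, se, float(p), n_cases, n_controls, stratum
        )

    converged, separation = True, False
    beta = se = p = np.nan
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
            for w in caught:
                if "separation" in str(w.message).lower():
                    separation = True
        beta = float(fit.params[1])
        se = float(fit.bse[1])
        p = float(fit.pvalues[1])
        if not np.isfinite(se) or se > 50:
            separation = True
    except Exception as exc:  # PerfectSeparationError, singular matrix, ...
        logger.warning("logistic fit failed for %s x %s: %s", test_id, phenotype, exc)
        converged = False
        if "separation" in str(exc).lower():
            separation = True
    return AssociationResult(
        test_id,
        phenotype,
        beta,
        se,
        p,
        n_cases,
        n_controls,
        stratum,
        converged=converged,
        separation=separation,
    )


def ivw_meta(results: list[AssociationResult]) -> AssociationResult:
    """Fixed-effect inverse-variance-weighted meta-analysis across strata.

    beta = sum(w_i b_i) / sum(w_i), se = sum(w_i)^(-1/2) with w_i = 1/se_i^2;
    two-sided normal p-value.  Strata with unreliable fits are dropped with a
    log note; a zero standard error is an error.
    """
    usable = [r for r in results if r.reliable and np.isfinite(r.se)]
    dropped = len(results) - len(usable)
    if dropped:
        logger.info("IVW meta: dropped %d unreliable strata", dropped)
    if not usable:
        raise ValueError("no stratum with a finite, reliable standard error")
    if any(r.se == 0 for r in usable):
        raise ValueError("zero standard error in a stratum")
    if len(usable) == 1:
        return usable[0]
    w = np.array([1.0 / r.se**2 for r in usable])
    b = np.array([r.beta for r in usable])
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    first = usable[0]
    return AssociationResult(
        first.test_id,
        first.phenotype,
        beta,
        se,
        p,
        sum(r.n_cases for r in usable),
        sum(r.n_controls for r in usable),
        stratum="meta",
    )


def burden_collapse(
    gene: str,
    variant_annotations: pd.DataFrame,
    dosages: pd.DataFrame,
    revel_min: float = 0.5,
    maf_max: float = 0.001,
) -> pd.Series:
    """Additive per-individual burden of qualifying rare variants in a gene.

    Qualifying variants are rare (MAF <= ``maf_max``) and either pLOF or
    missense with REVEL >= ``revel_min``.  ``variant_annotations`` is indexed
    by variant id with columns gene, cds_labels (comma-joined), revel, maf.
    Missing genotypes contribute 0 to the sum.
    """
    ann = variant_annotations[variant_annotations["gene"] == gene]
    qualifying = []
    for vid, row in ann.iterrows():
        if row["maf"] > maf_max:
            continue
        labels = set(str(row["cds_labels"]).split(",")) if pd.notna(row["cds_labels"]) else set()
        if "pLOF" in labels:
            qualifying.append(vid)
        elif "missense" in labels and pd.notna(row.get("revel")) and row["revel"] >= revel_min:
            qualifying.append(vid)
    qualifying = [v for v in qualifying if v in dosages.columns]
    if not qualifying:
        return pd.Series(0.0, index=dosages.index, name=f"{gene}_burden")
    burden = dosages[qualifying].fillna(0).sum(axis=1)
    burden.name = f"{gene}_burden"
    return burden


def phewas_thresholds(
    n_variants: int,
    n_phenotypes: int,
    alpha: float = 0.05,
    fdr_level: float = 0.1,
) -> tuple[float, float]:
    """Significance lines for a PheWAS panel.

    Bonferroni: alpha / (n_variants x n_phenotypes).  The plotted FDR line
    is fdr_level / n_phenotypes.
    """
    if n_variants <= 0 or n_phenotypes <= 0:
        raise ValueError("counts must be positive")
    return alpha / (n_variants * n_phenotypes), fdr_level / n_phenotypes


def bh_fdr(p_values: list[float] | np.ndarray, fdr_level: float = 0.1) -> np.ndarray:
    """Benjamini-Hochberg step-up: boolean mask of discoveries."""
    from statsmodels.stats.multitest import multipletests

    reject, *_ = multipletests(np.asarray(p_values), alpha=fdr_level, method="fdr_bh")
    return reject


def run_phewas(
    dosages: pd.DataFrame,
    covariates: pd.DataFrame,
    events: pd.DataFrame,
    phenotype_codes: list[str],
    strata: pd.Series | None = None,
    covariate_names: list[str] | None = None,
    min_case_dates: int = 2,
    min_alt_alleles: int = 5,
    max_missing_frac: float = 0.5,
    min_cases: int = 20,
    firth: bool = False,
) -> pd.DataFrame:
    """Full PheWAS: every variant column against every phenotype code.

    ``strata`` maps individuals to ancestry strata; per-stratum results are
    IVW-combined.  Returns a tidy DataFrame (one row per tested pair, plus
    untested pairs with their failure reasons).
    """
    covariate_names = covariate_names or [
        c for c in DEFAULT_COVARIATES if c in covariates.columns
    ]
    cov = covariates[covariate_names]
    if strata is None:
        strata = pd.Series("all", index=dosages.index)
    rows = []
    for code in phenotype_codes:
        status = derive_case_control(
            events, code, dosages.index, min_case_dates=min_case_dates
        )
        for vid in dosages.columns:
            ok, reasons = eligibility_filters(
                dosages[vid],
                status,
                min_alt_alleles=min_alt_alleles,
                max_missing_frac=max_missing_frac,
                min_cases=min_cases,
            )
            if not ok:
                rows.append(
                    {
                        "test_id": vid,
                        "phenotype": code,
                        "tested": False,
                        "reasons": ",".join(reasons),
                    }
                )
                continue
            per_stratum = []
            for label in strata.dropna().unique():
                idx = strata[strata == label].index
                sub_status = status.reindex(idx)
                sub_d = dosages[vid].reindex(idx)
                keep = sub_status.isin(["case", "control"]) & sub_d.notna()
                if (sub_d[keep].sum() or 0) < 1 or (sub_status[keep] == "case").sum() < 1:
                    continue  # monomorphic or caseless stratum: drop
                res = logistic_assoc(
                    sub_d,
                    sub_status,
                    cov.reindex(idx),
                    test_id=vid,
                    phenotype=code,
                    stratum=str(label),
                    firth=firth,
                )
                if res.reliable:
                    per_stratum.append(res)
            if not per_stratum:
                rows.append(
                    {
                        "test_id": vid,
                        "phenotype": code,
                        "tested": False,
                        "reasons": "no_reliable_stratum",
                    }
                )
                continue
            meta = ivw_meta(per_stratum)
            row = meta.to_dict()
            row["tested"] = True
            row["reasons"] = ""
            rows.append(row)
    return pd.DataFrame(rows)
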