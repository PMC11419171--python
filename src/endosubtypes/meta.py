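"""Random-effects meta-analysis across strata, with controls.

Per-stratum effect estimates for each (variant, phenotype) pair are
combined with the DerSimonian-Laird estimator:

    Q    = sum w_i (b_i - b_FE)^2,   w_i = 1/se_i^2
    tau2 = max(0, (Q - (k-1)) / (sum w_i - sum w_i^2 / sum w_i))
    b_RE = sum w*_i b_i / sum w*_i,  w*_i = 1 / (se_i^2 + tau2)

so whenever Q <= k-1 the estimate collapses to the fixed-effect
inverse-variance meta-analysis exactly. Random effects are used because
the strata span genetically distinct ancestry groups.

Controls:

* positive control — all endometriosis cases pooled into one phenotype,
  the replication baseline;
* negative control — cases randomly reassigned to clusters preserving
  the exact per-dataset cluster sizes, which should carry only the
  diluted pooled signal.

``significance_summary`` condenses locus-level results (min p over lead
+ tags) against the genome-wide 5e-8 and candidate-locus Bonferroni
0.05/39 thresholds (strict inequalities) and counts loci where a cluster
phenotype beats the positive control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import LocusSet

__all__ = [
    "MetaResult",
    "dl_meta",
    "meta_analyze",
    "negative_control",
    "significance_summary",
    "format_count_percent",
]

GENOME_WIDE_ALPHA = 5e-8


@dataclass
class MetaResult:
    beta: float
    se: float
    p: float
    Q: float
    tau2: float
    I2: float
    k_strata: int


def dl_meta(betas, ses) -> MetaResult:
    """DerSimonian-Laird random-effects combination of per-stratum
    estimates; strata with non-finite beta or se are dropped, and a
    single stratum is returned unchanged (tau2 = 0)."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    ok = np.isfinite(betas) & np.isfinite(ses) & (ses > 0)
    betas, ses = betas[ok], ses[ok]
    k = len(betas)
    if k == 0:
        return MetaResult(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, 0)
    w = 1.0 / ses ** 2
    b_fe = float(np.sum(w * betas) / np.sum(w))
    Q = float(np.sum(w * (betas - b_fe) ** 2))
    if k == 1:
        beta, se, tau2, I2 = float(betas[0]), float(ses[0]), 0.0, 0.0
    else:
        denom = np.sum(w) - np.sum(w ** 2) / np.sum(w)
        tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
        w_star = 1.0 / (ses ** 2 + tau2)
        beta = float(np.sum(w_star * betas) / np.sum(w_star))
        se = float(np.sqrt(1.0 / np.sum(w_star)))
        I2 = max(0.0, (Q - (k - 1)) / Q) if Q > 0 else 0.0
    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    return MetaResult(beta, se, p, Q, tau2, float(I2), k)


def meta_analyze(assoc_results: pd.DataFrame) -> pd.DataFrame:
    """DL meta-analysis of per-stratum association rows, one output row
    per (phenotype, variant). Input needs columns variant, phenotype,
    stratum, beta, se (n_case/n_control summed when present)."""
    rows = []
    has_n = {"n_case", "n_control"} <= set(assoc_results.columns)
    for (pheno, variant), part in assoc_results.groupby(["phenotype", "variant"],
                                                        sort=False):
        m = dl_meta(part["beta"].to_numpy(), part["se"].to_numpy())
        row = {
            "variant": variant, "phenotype": pheno, "beta": m.beta, "se": m.se,
            "p": m.p, "Q": m.Q, "tau2": m.tau2, "I2": m.I2, "k_strata": m.k_strata,
        }
        if has_n:
            ok = part["beta"].notna()
            row["n_case"] = int(part.loc[ok, "n_case"].sum())
            row["n_control"] = int(part.loc[ok, "n_control"].sum())
        rows.append(row)
    return pd.DataFrame(rows)


def negative_control(
    labels: pd.Series,
    datasets: pd.Series | None = None,
    seed: int = 0,
) -> pd.Series:
    """Randomly reassign case cluster labels, preserving the exact
    multiset of cluster sizes (per dataset when ``datasets`` is given).
    The five negative-control analyses then have the same case and
    control counts as the real ones."""
    rng = np.random.default_rng(seed)
    values = labels.to_numpy().copy()
    if datasets is None:
        rng.shuffle(values)
    else:
        ds = datasets.reindex(labels.index).to_numpy()
        for d in pd.unique(ds):
            sel = np.flatnonzero(ds == d)
            values[sel] = values[sel[rng.permutation(len(sel))]]
    return pd.Series(values, index=labels.index, name=labels.name)


def format_count_percent(count: int, total: int, digits: int = 0) -> str:
    """Report formatting for "count (percent%)" cells, e.g.
    441 of 4078 -> "441 (10.8%)" at digits=1."""
    pct = 100.0 * count / total
    return f"{count:,} ({pct:.{digits}f}%)"


def significance_summary(
    meta_results: pd.DataFrame,
    locus_set: LocusSet,
    positive_control: str = "positive_control",
    negative_prefix: str = "negative_control",
    bonferroni_n: int = 39,
    alpha: float = 0.05,
    gw_alpha: float = GENOME_WIDE_ALPHA,
) -> pd.DataFrame:
    """Per-phenotype locus-level significance counts.

    The locus p-value is the minimum meta p over the lead and its tags;
    thresholds are strict (< alpha/bonferroni_n, < gw_alpha). Output has
    one row per phenotype with columns: loci_tested,
    bonferroni_significant, genome_wide_significant,
    stronger_than_positive_control, significant_fraction (formatted
    "x / N (p%)"). Negative-control phenotypes report their own counts;
    the stronger-than-baseline comparison is left NaN for the positive
    control itself, and empty (with a warning) when it is absent.
    """
    import warnings

    bonf = alpha / bonferroni_n
    leads = locus_set.leads
    # locus-level min p per phenotype
    member_of = {}
    for lead in leads:
        for rsid in locus_set.members(lead):
            member_of.setdefault(rsid, []).append(lead)
    mr = meta_results.dropna(subset=["p"]).copy()
    locus_p: dict[tuple[str, str], float] = {}
    for _, row in mr.iterrows():
        for lead in member_of.get(row["variant"], []):
            key = (row["phenotype"], lead)
            locus_p[key] = min(locus_p.get(key, np.inf), row["p"])

    phenos = list(dict.fromkeys(meta_results["phenotype"]))
    has_pc = positive_control in phenos
    if not has_pc:
        warnings.warn("positive control missing: baseline comparison left empty",
                      stacklevel=2)
    rows = []
    for pheno in phenos:
        pvals = {lead: locus_p.get((pheno, lead), np.nan) for lead in leads}
        tested = int(np.sum([np.isfinite(v) for v in pvals.values()]))
        n_bonf = int(np.sum([v < bonf for v in pvals.values() if np.isfinite(v)]))
        n_gw = int(np.sum([v < gw_alpha for v in pvals.values() if np.isfinite(v)]))
        if has_pc and pheno != positive_control:
            stronger = int(np.sum([
                np.isfinite(pvals[l]) and np.isfinite(locus_p.get((positive_control, l), np.nan))
                and pvals[l] < locus_p[(positive_control, l)] for l in leads
            ]))
        else:
            stronger = np.nan
        rows.append({
            "phenotype": pheno,
            "loci_tested": tested,
            "bonferroni_significant": n_bonf,
            "genome_wide_significant": n_gw,
            "stronger_than_positive_control": stronger,
            "significant_fraction": f"{n_bonf} / {bonferroni_n} "
                                    f"({100 * n_bonf / bonferroni_n:.0f}%)",
            "is_negative_control": pheno.startswith(negative_prefix),
        })
    return pd.DataFrame(rows)
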