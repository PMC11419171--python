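"""Cluster-stratified candidate-locus case-control association.

Candidate loci are lead SNPs expanded with tag SNPs in LD (same
chromosome, base-pair distance < 0.5 Mb and r^2 > 0.1 against a
reference genotype panel). Association within each ancestry x dataset
stratum is a covariate-adjusted logistic score test: the null model
``case ~ age + first four principal components`` is fitted once per
phenotype and stratum, and each variant's dosage is tested through the
efficient score

    U = g' (y - mu),   V = g'Wg - g'WX (X'WX)^{-1} X'Wg,

with W = diag(mu(1-mu)) from the null fit; U^2/V is chi-square(1). The
effect size is the one-step estimate U/V with standard error 1/sqrt(V)
(a full maximum-likelihood refit is available per variant), and an
optional saddlepoint approximation replaces the normal tail for heavily
imbalanced case:control ratios. This preserves the statistical intent of
large-scale mixed-model score tests at desk scale; there is no
relatedness in the cohorts analysed here, so no genetic relatedness
matrix is involved.

Missing dosages are mean-imputed per variant; variants monomorphic after
imputation are skipped with a reason, never silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GenotypeMatrix",
    "LocusSet",
    "compute_pcs",
    "ld_expand",
    "LogisticNull",
    "logistic_assoc",
    "run_stratified_assoc",
]


@dataclass
class GenotypeMatrix:
    """Subjects x variants dosage matrix (0..2, NaN = missing)."""

    subject_ids: np.ndarray
    variants: pd.DataFrame  # rsid, chrom, pos (1-based), ref, alt, locus_label
    dosages: np.ndarray  # (n_subjects, n_variants) float

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.subject_ids), len(self.variants)):
            raise ValueError("dosage shape mismatch")
        if (self.variants["pos"] < 1).any():
            raise ValueError("positions are 1-based; pos must be >= 1")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.nansum(bad) > 0:
            raise ValueError("dosages must lie in [0, 2] or be missing")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def rsids(self) -> np.ndarray:
        return self.variants["rsid"].to_numpy()

    def variant_index(self, rsid: str) -> int:
        idx = np.flatnonzero(self.rsids == rsid)
        if len(idx) == 0:
            raise KeyError(f"variant {rsid!r} not in matrix")
        return int(idx[0])

    def dosage(self, rsid: str) -> np.ndarray:
        return self.dosages[:, self.variant_index(rsid)]

    def subset_subjects(self, ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"subjects not in genotype matrix: {missing[:3]}")
        rows = np.array([pos[s] for s in ids], dtype=int)
        return GenotypeMatrix(np.asarray(ids), self.variants.copy(),
                              self.dosages[rows])

    def subset_variants(self, rsids: Sequence[str]) -> "GenotypeMatrix":
        cols = np.array([self.variant_index(r) for r in rsids], dtype=int)
        return GenotypeMatrix(self.subject_ids.copy(),
                              self.variants.iloc[cols].reset_index(drop=True),
                              self.dosages[:, cols])

    def allele_freq(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.nanmean(self.dosages, axis=0) / 2.0


def _impute_mean(dosages: np.ndarray) -> np.ndarray:
    out = np.array(dosages, dtype=float, copy=True)
    if np.isnan(out).any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            col_mean = np.nanmean(out, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        nan_r, nan_c = np.where(np.isnan(out))
        out[nan_r, nan_c] = col_mean[nan_c]
    return out


# ---------------------------------------------------------------------------
# principal components
# ---------------------------------------------------------------------------

def ld_prune_indices(dosages: np.ndarray, r2_max: float = 0.2) -> np.ndarray:
    """Greedy LD pruning: keep each polymorphic variant whose squared
    correlation with every previously kept variant is <= ``r2_max``.

    Used before PCA so that correlated tag pairs do not masquerade as
    population-structure axes (on a candidate-locus panel a tag pair is a
    dominant eigenvector that would absorb the association signal)."""
    X = _impute_mean(dosages)
    sd = X.std(axis=0)
    keep: list[int] = []
    for j in range(X.shape[1]):
        if sd[j] == 0:
            continue
        zj = (X[:, j] - X[:, j].mean()) / sd[j]
        ok = True
        for k in keep:
            zk = (X[:, k] - X[:, k].mean()) / sd[k]
            if (zj @ zk / len(zj)) ** 2 > r2_max:
                ok = False
                break
        if ok:
            keep.append(j)
    return np.asarray(keep, dtype=int)


def compute_pcs(G: GenotypeMatrix, n_pcs: int = 4) -> np.ndarray:
    """Principal-component scores of the frequency-standardized dosage
    matrix (mean-imputed, centered, scaled by sqrt(2p(1-p))); columns are
    mutually orthogonal."""
    X = _impute_mean(G.dosages)
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < n_pcs:
        raise ValueError(
            f"need >= {n_pcs} non-monomorphic variants for {n_pcs} PCs, "
            f"have {int(poly.sum())}")
    Xs = (X[:, poly] - 2 * p[poly]) / np.sqrt(2 * p[poly] * (1 - p[poly]))
    U, s, _ = np.linalg.svd(Xs, full_matrices=False)
    pcs = U[:, :n_pcs] * s[:n_pcs]
    # deterministic sign: largest-magnitude loading positive
    for j in range(pcs.shape[1]):
        i = np.argmax(np.abs(pcs[:, j]))
        if pcs[i, j] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs


# ---------------------------------------------------------------------------
# LD expansion
# ---------------------------------------------------------------------------

@dataclass
class LocusSet:
    """Lead SNPs plus their LD tags. ``table`` has one row per member
    variant (the lead itself included with r2=1, distance=0)."""

    table: pd.DataFrame  # locus_label, lead_rsid, rsid, chrom, pos, r2, distance

    @property
    def leads(self) -> list[str]:
        return list(dict.fromkeys(self.table["lead_rsid"]))

    @property
    def all_rsids(self) -> list[str]:
        return list(dict.fromkeys(self.table["rsid"]))

    def members(self, lead_rsid: str) -> list[str]:
        return self.table.loc[self.table["lead_rsid"] == lead_rsid, "rsid"].tolist()


def ld_expand(
    reference: GenotypeMatrix,
    leads: Sequence[str],
    window: int = 500_000,
    r2_min: float = 0.1,
) -> LocusSet:
    """Expand each lead SNP with tags on the same chromosome at strict
    base-pair distance < ``window`` and squared dosage correlation
    r^2 > ``r2_min`` in the reference panel.

    r^2 is the squared Pearson correlation of mean-imputed dosage
    vectors, so it is symmetric and invariant to allele flips. A lead
    monomorphic in the reference yields a lead-only locus with a warning.
    """
    X = _impute_mean(reference.dosages)
    var = X.var(axis=0)
    variants = reference.variants
    rows = []
    for lead in leads:
        li = reference.variant_index(lead)
        lead_row = variants.iloc[li]
        label = lead_row.get("locus_label", lead) or lead
        rows.append((label, lead, lead, lead_row["chrom"], int(lead_row["pos"]), 1.0, 0))
        if var[li] == 0:
            warnings.warn(f"lead {lead} monomorphic in reference; no tags", stacklevel=2)
            continue
        g_lead = X[:, li]
        same_chrom = (variants["chrom"] == lead_row["chrom"]).to_numpy()
        dist = np.abs(variants["pos"].to_numpy() - int(lead_row["pos"]))
        cand = np.flatnonzero(same_chrom & (dist < window) & (var > 0))
        for ci in cand:
            if ci == li:
                continue
            r = np.corrcoef(g_lead, X[:, ci])[0, 1]
            r2 = float(r * r)
            if r2 > r2_min:
                crow = variants.iloc[ci]
                rows.append((label, lead, crow["rsid"], crow["chrom"],
                             int(crow["pos"]), r2, int(dist[ci])))
    table = pd.DataFrame(
        rows, columns=["locus_label", "lead_rsid", "rsid", "chrom", "pos",
                       "r2", "distance"],
    )
    return LocusSet(table)


# ---------------------------------------------------------------------------
# logistic score test
# ---------------------------------------------------------------------------

class LogisticNull:
    """Null logistic model ``y ~ 1 + covariates`` fitted once; the score
    test for any dosage vector then needs only matrix products."""

    def __init__(self, y: np.ndarray, covariates: np.ndarray | None = None):
        import statsmodels.api as sm

        y = np.asarray(y, dtype=float)
        if covariates is None:
            X = np.ones((len(y), 1))
        else:
            covariates = np.asarray(covariates, dtype=float)
            if covariates.ndim == 1:
                covariates = covariates[:, None]
            X = np.column_stack([np.ones(len(y)), covariates])
        if y.min() == y.max():
            raise ValueError("need both cases and controls in the null model")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        self.y = y
        self.X = X
        self.mu = np.clip(fit.predict(X), 1e-12, 1 - 1e-12)
        self.W = self.mu * (1 - self.mu)
        self.resid = y - self.mu
        XtWX = X.T @ (X * self.W[:, None])
        self._XtWX_inv = np.linalg.inv(XtWX)

    def score_test(self, G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Efficient score U and its variance V for each column of G."""
        G = np.asarray(G, dtype=float)
        if G.ndim == 1:
            G = G[:, None]
        U = G.T @ self.resid
        WG = G * self.W[:, None]
        A = self.X.T @ WG  # (k, V)
        V = np.einsum("ij,ij->j", G, WG) - np.einsum("ij,ij->j", A, self._XtWX_inv @ A)
        return U, V

    def spa_pvalue(self, g: np.ndarray, u: float) -> float:
        """Saddlepoint approximation to P(|S| >= |u|) for the score
        S = g'(y - mu), sharper than the normal tail under case:control
        imbalance (Lugannani-Rice formula)."""
        g = np.asarray(g, dtype=float)
        mu = self.mu

        def K(t):
            return np.sum(np.log1p(mu * (np.exp(g * t) - 1.0))) - t * np.sum(g * mu)

        def K1(t):
            e = np.exp(g * t)
            return np.sum(mu * g * e / (1 + mu * (e - 1))) - np.sum(g * mu)

        def K2(t):
            e = np.exp(g * t)
            denom = (1 + mu * (e - 1)) ** 2
            return np.sum(mu * (1 - mu) * g ** 2 * e / denom)

        def normal_tail(s):
            return float(stats.norm.sf(abs(s) / np.sqrt(K2(0.0))))

        def tail(s):
            """P(S >= s) for s > 0, P(S <= s) for s < 0 (Lugannani-Rice).

            K' is increasing with K'(0) = 0 (centered g), so the
            saddlepoint has the sign of s; the bracket is expanded until
            it straddles the root."""
            if s == 0:
                return 0.5
            sign = 1.0 if s > 0 else -1.0
            hi = sign
            for _ in range(80):
                if sign * (K1(hi) - s) > 0:
                    break
                hi *= 2.0
                if abs(hi) > 1e8:
                    return normal_tail(s)
            try:
                t_hat = optimize.brentq(lambda t: K1(t) - s,
                                        min(0.0, hi), max(0.0, hi), xtol=1e-12)
            except ValueError:
                return normal_tail(s)
            w = np.sign(t_hat) * np.sqrt(max(2 * (t_hat * s - K(t_hat)), 0.0))
            v = t_hat * np.sqrt(max(K2(t_hat), 1e-300))
            if abs(w) < 1e-6 or v == 0:
                return normal_tail(s)
            z = w + np.log(v / w) / w
            return float(stats.norm.sf(z)) if s > 0 else float(stats.norm.cdf(z))

        return float(min(1.0, tail(abs(u)) + tail(-abs(u))))


def logistic_assoc(
    g: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    beta_method: str = "onestep",
    spa: bool = False,
    null: LogisticNull | None = None,
) -> dict:
    """Single-variant covariate-adjusted association.

    Returns a dict with beta, se, stat, p, n_case, n_control and a
    ``note`` (skip / separation flags). ``beta_method="full"`` refits the
    logistic model with the dosage term by maximum likelihood for the
    effect estimate; the p-value is always from the score test.
    """
    g = _impute_mean(np.asarray(g, dtype=float)[:, None])[:, 0]
    y = np.asarray(y, dtype=float)
    n_case, n_control = int(y.sum()), int((1 - y).sum())
    base = {"n_case": n_case, "n_control": n_control}
    if g.min() == g.max():
        return {**base, "beta": np.nan, "se": np.nan, "stat": np.nan,
                "p": np.nan, "note": "skipped: monomorphic dosage"}
    if null is None:
        null = LogisticNull(y, covariates)
    U, V = null.score_test(g)
    u, v = float(U[0]), float(V[0])
    if v <= 0:
        return {**base, "beta": np.nan, "se": np.nan, "stat": np.nan,
                "p": np.nan, "note": "skipped: zero score variance"}
    stat = u * u / v
    p = float(stats.chi2.sf(stat, df=1))
    if spa:
        p = null.spa_pvalue(g - g.mean(), u)
    beta, se, note = u / v, 1.0 / np.sqrt(v), ""
    if beta_method == "full":
        import statsmodels.api as sm

        Xfull = np.column_stack([null.X, g])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, Xfull).fit(disp=0, maxiter=200)
            if np.isfinite(fit.params[-1]) and np.isfinite(fit.bse[-1]) \
                    and abs(fit.params[-1]) < 20:
                beta, se = float(fit.params[-1]), float(fit.bse[-1])
            else:
                note = "separation: one-step estimate reported"
        except Exception:
            note = "full fit failed: one-step estimate reported"
    elif beta_method != "onestep":
        raise ValueError(f"unknown beta_method {beta_method!r}")
    return {**base, "beta": float(beta), "se": float(se), "stat": float(stat),
            "p": p, "note": note}


# ---------------------------------------------------------------------------
# stratified driver
# ---------------------------------------------------------------------------

def run_stratified_assoc(
    G: GenotypeMatrix,
    subjects: pd.DataFrame,
    phenotypes: Mapping[str, Sequence[str]],
    control_ids: Sequence[str],
    test_rsids: Sequence[str] | None = None,
    n_pcs: int = 4,
    use_age: bool = True,
    beta_method: str = "onestep",
    min_stratum_cases: int = 5,
    pc_prune_r2: float = 0.2,
) -> pd.DataFrame:
    """Per-phenotype, per-stratum association over the requested variants.

    ``phenotypes`` maps a phenotype name (a cluster id, the positive
    control, a negative control...) to its case subject ids; controls are
    shared across phenotypes. Strata are the ancestry x dataset cells
    present among the analysed subjects. Principal components are
    computed within each stratum from the full genotype matrix; strata
    with fewer cases than ``min_stratum_cases`` are skipped with a note
    row.
    """
    subj = subjects.set_index("subject_id")
    control_ids = list(control_ids)
    test_rsids = list(test_rsids) if test_rsids is not None else list(G.rsids)
    all_ids = list(G.subject_ids)
    id_pos = {s: i for i, s in enumerate(all_ids)}

    for name, ids in phenotypes.items():
        if len(ids) == 0:
            raise ValueError(f"phenotype {name!r} has no cases")

    strata = (
        subj.loc[subj.index.isin(all_ids), ["ancestry", "dataset"]]
        .drop_duplicates().itertuples(index=False)
    )
    var_cols = np.array([G.variant_index(r) for r in test_rsids], dtype=int)
    vmeta = G.variants.iloc[var_cols]
    pruned = ld_prune_indices(G.dosages, pc_prune_r2)
    results = []
    for ancestry, dataset in strata:
        stratum = f"{ancestry}:{dataset}"
        member = subj.index[(subj["ancestry"] == ancestry)
                            & (subj["dataset"] == dataset)]
        member = [s for s in member if s in id_pos]
        ctrl = [s for s in control_ids if s in set(member)]
        rows_all = np.array([id_pos[s] for s in member], dtype=int)
        # stratum PCs from the LD-pruned variant panel
        sub_G = GenotypeMatrix(np.asarray(member),
                               G.variants.iloc[pruned].reset_index(drop=True),
                               G.dosages[np.ix_(rows_all, pruned)])
        pcs_n = n_pcs
        while pcs_n > 0:
            try:
                pcs = compute_pcs(sub_G, pcs_n)
                break
            except ValueError:
                pcs_n -= 1
        else:
            pcs = np.zeros((len(member), 0))
        pc_of = {s: pcs[i] for i, s in enumerate(member)}

        for pheno, case_ids in phenotypes.items():
            cases = [s for s in case_ids if s in set(member)]
            if len(cases) < min_stratum_cases or len(ctrl) == 0:
                continue  # skipped stratum: too few cases or no controls
            ids = cases + ctrl
            y = np.concatenate([np.ones(len(cases)), np.zeros(len(ctrl))])
            rows = np.array([id_pos[s] for s in ids], dtype=int)
            covs = [np.vstack([pc_of[s] for s in ids])] if pcs_n else []
            if use_age:
                covs.append(subj.loc[ids, "age"].to_numpy(float)[:, None])
            covariates = np.hstack(covs) if covs else None
            Gsub = _impute_mean(G.dosages[np.ix_(rows, var_cols)])
            null = LogisticNull(y, covariates)
            U, V = null.score_test(Gsub)
            for j, rsid in enumerate(test_rsids):
                gcol = Gsub[:, j]
                meta = vmeta.iloc[j]
                if gcol.min() == gcol.max():
                    results.append((rsid, meta["chrom"], int(meta["pos"]),
                                    meta["alt"], pheno, stratum, np.nan, np.nan,
                                    np.nan, np.nan, len(cases), len(ctrl),
                                    "skipped: monomorphic"))
                    continue
                u, v = float(U[j]), float(V[j])
                if v <= 0:
                    results.append((rsid, meta["chrom"], int(meta["pos"]),
                                    meta["alt"], pheno, stratum, np.nan, np.nan,
                                    np.nan, np.nan, len(cases), len(ctrl),
                                    "skipped: zero score variance"))
                    continue
                stat = u * u / v
                p = float(stats.chi2.sf(stat, df=1))
                if beta_method == "full":
                    res = logistic_assoc(gcol, y, covariates,
                                         beta_method="full", null=null)
                    beta, se, note = res["beta"], res["se"], res["note"]
                else:
                    beta, se, note = u / v, 1.0 / np.sqrt(v), ""
                results.append((rsid, meta["chrom"], int(meta["pos"]), meta["alt"],
                                pheno, stratum, beta, se, stat, p,
                                len(cases), len(ctrl), note))
    out = pd.DataFrame(
        results,
        columns=["variant", "chrom", "pos", "effect_allele", "phenotype",
                 "stratum", "beta", "se", "stat", "p", "n_case", "n_control",
                 "note"],
    )
    return out
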