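"""Synthetic EHR-linked cohort generator with planted disease subtypes.

Every downstream stage of the pipeline (feature extraction, clustering,
label transfer, stratified association, meta-analysis) is exercised on
cohorts produced here, because the source biobanks are access-controlled.

The generative model:

* Subjects are ``n_controls`` controls plus ``n_cases_per_subtype[k]``
  cases for each latent subtype k (exact counts by construction —
  case-control ascertainment, not forward disease simulation).
* Binary clinical features are conditionally independent given the
  subtype: feature j is Bernoulli(p_jk) for subtype-k cases and
  Bernoulli(p_j0) for controls.
* Genotypes are Hardy-Weinberg for controls, Binomial(2, maf).  Cases of
  subtype k are sampled retrospectively: genotype g in {0,1,2} is drawn
  with probability proportional to HWE(g) * exp(beta_k * g), the
  case-conditional genotype distribution implied by a logistic disease
  model with per-subtype log odds ratio beta_k.
* ICD codes are emitted from positive feature flags (one code per
  positive flag, kept with probability ``icd_sensitivity``); cases
  additionally emit a bare endometriosis code (ICD-10 "N80") so the
  feature-extraction case rule recovers exactly the simulated cases.
  With sensitivity 1.0, ``extract_features(emit_icd_records(X)) == X``.

Ancestry strata get independent genotype draws and optionally their own
allele frequencies, to give the meta-analysis real heterogeneity to work
with.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureCatalog, PhenotypeMatrix, default_catalog

__all__ = [
    "VariantSpec",
    "SimConfig",
    "SyntheticTruth",
    "CohortBundle",
    "simulate_cohort",
    "simulate_genotypes",
    "emit_icd_records",
    "block_prevalence",
    "expected_case_allele_freq",
]


@dataclass(frozen=True)
class VariantSpec:
    """One simulated biallelic SNP with per-subtype effects.

    ``beta_k[k]`` is the log odds ratio of the alternate allele in
    subtype k; ``maf_by_stratum`` optionally overrides ``maf`` per
    ancestry label to create between-stratum heterogeneity.
    """

    rsid: str
    chrom: str
    pos: int
    maf: float
    beta_k: tuple[float, ...]
    ref: str = "A"
    alt: str = "G"
    locus_label: str | None = None
    maf_by_stratum: Mapping[str, float] | None = None
    #: simulate LD: copy this lead variant's genotypes, re-drawing each
    #: subject from HWE with probability ``tag_flip`` (so r ~= 1 - tag_flip)
    tag_of: str | None = None
    tag_flip: float = 0.0

    def stratum_maf(self, ancestry: str) -> float:
        if self.maf_by_stratum and ancestry in self.maf_by_stratum:
            return float(self.maf_by_stratum[ancestry])
        return float(self.maf)


@dataclass
class SimConfig:
    """Generator parameters. Probabilities are checked on construction of
    the cohort; errors name the offending field."""

    n_controls: int
    n_cases_per_subtype: Sequence[int]
    feature_prevalence: np.ndarray  # (n_features, K) Bernoulli p_jk for cases
    control_feature_prevalence: np.ndarray  # (n_features,) p_j0
    variant_specs: Sequence[VariantSpec] = field(default_factory=list)
    strata: Sequence[tuple[str, float]] = (("EUR", 1.0),)
    feature_names: Sequence[str] | None = None
    dataset: str = "SYN"
    icd_sensitivity: float = 1.0
    seed: int = 0

    @property
    def n_subtypes(self) -> int:
        return len(self.n_cases_per_subtype)

    @property
    def subtype_proportions(self) -> np.ndarray:
        counts = np.asarray(self.n_cases_per_subtype, dtype=float)
        return counts / counts.sum()

    def validate(self) -> None:
        if self.n_controls < 0:
            raise ValueError("n_controls: must be >= 0")
        if len(self.n_cases_per_subtype) == 0 or any(c < 0 for c in self.n_cases_per_subtype):
            raise ValueError("n_cases_per_subtype: need non-negative counts for >= 1 subtype")
        p = np.asarray(self.feature_prevalence, dtype=float)
        p0 = np.asarray(self.control_feature_prevalence, dtype=float)
        if p.ndim != 2 or p.shape[1] != self.n_subtypes:
            raise ValueError("feature_prevalence: expected matrix (n_features, K)")
        if p0.shape != (p.shape[0],):
            raise ValueError("control_feature_prevalence: length must match feature_prevalence rows")
        if ((p < 0) | (p > 1)).any():
            raise ValueError("feature_prevalence: probabilities must be in [0, 1]")
        if ((p0 < 0) | (p0 > 1)).any():
            raise ValueError("control_feature_prevalence: probabilities must be in [0, 1]")
        if not 0 <= self.icd_sensitivity <= 1:
            raise ValueError("icd_sensitivity: must be in [0, 1]")
        fracs = np.array([f for _, f in self.strata], dtype=float)
        if (fracs < 0).any() or not np.isclose(fracs.sum(), 1.0):
            raise ValueError("strata: fractions must be non-negative and sum to 1")
        for v in self.variant_specs:
            if not 0 < v.maf <= 0.5:
                raise ValueError(f"variant_specs[{v.rsid}].maf: must be in (0, 0.5]")
            if len(v.beta_k) != self.n_subtypes:
                raise ValueError(f"variant_specs[{v.rsid}].beta_k: length must equal K")
            if not 0 <= v.tag_flip <= 1:
                raise ValueError(f"variant_specs[{v.rsid}].tag_flip: must be in [0, 1]")
            if v.maf_by_stratum:
                for anc, m in v.maf_by_stratum.items():
                    if not 0 < m <= 0.5:
                        raise ValueError(f"variant_specs[{v.rsid}].maf_by_stratum[{anc}]: must be in (0, 0.5]")
        if self.feature_names is not None and len(self.feature_names) != p.shape[0]:
            raise ValueError("feature_names: length must match feature_prevalence rows")


@dataclass
class SyntheticTruth:
    """Hidden ground truth retained for test harnesses."""

    subtype: pd.Series  # subject_id -> subtype index (int) or -1 for controls
    variant_betas: dict[str, tuple[float, ...]]  # rsid -> beta_k
    feature_prevalence: pd.DataFrame  # feature x subtype p_jk (+ control column)

    def case_subtypes(self) -> pd.Series:
        return self.subtype[self.subtype >= 0]


@dataclass
class CohortBundle:
    """Everything the pipeline consumes, plus the hidden truth."""

    subjects: pd.DataFrame  # subject_id, age, sex, ancestry, dataset
    icd: pd.DataFrame  # subject_id, vocabulary, code
    genotypes: "GenotypeMatrix"
    truth: SyntheticTruth
    feature_flags: PhenotypeMatrix  # pre-ICD binary flags (simulator internal)

    def __post_init__(self) -> None:
        ids = self.subjects["subject_id"]
        if ids.duplicated().any():
            raise ValueError("duplicate subject ids in cohort")
        extra = set(self.icd["subject_id"]) - set(ids)
        if extra:
            raise ValueError(f"ICD records for unknown subjects: {sorted(extra)[:3]}")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _draw_ancestry(rng: np.random.Generator, strata, n: int) -> np.ndarray:
    labels = np.array([a for a, _ in strata], dtype=object)
    fracs = np.array([f for _, f in strata], dtype=float)
    return rng.choice(labels, size=n, p=fracs / fracs.sum())


def block_prevalence(n_features: int = 17, n_subtypes: int = 5,
                     p_high: float = 0.8, p_low: float = 0.05
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Block-structured planted prevalences: feature j is elevated
    (``p_high``) in subtype ``j mod K`` and baseline (``p_low``)
    elsewhere and in controls. Returns (p_jk, p_j0)."""
    p_jk = np.full((n_features, n_subtypes), p_low)
    for j in range(n_features):
        p_jk[j, j % n_subtypes] = p_high
    return p_jk, np.full(n_features, p_low)


def expected_case_allele_freq(maf: float, beta: float) -> float:
    """Closed-form alternate-allele frequency among cases under
    retrospective sampling: sum_g (g/2) HWE(g) e^{beta g} / sum_g HWE(g) e^{beta g}."""
    g = np.arange(3)
    hwe = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2])
    w = hwe * np.exp(beta * g)
    return float((g / 2 * w).sum() / w.sum())


def simulate_genotypes(
    subjects: pd.DataFrame,
    truth_subtype: pd.Series,
    variant_specs: Sequence[VariantSpec],
    seed: int,
) -> "GenotypeMatrix":
    """Genotype dosage matrix under HWE (controls) / retrospective
    case-conditional sampling (cases).  Deterministic given the seed."""
    from .assoc import GenotypeMatrix  # local import: assoc depends on nothing here

    rng = np.random.default_rng(seed)
    ids = subjects["subject_id"].to_numpy()
    anc = subjects["ancestry"].to_numpy()
    subtype = truth_subtype.reindex(ids).to_numpy()
    n, v = len(ids), len(variant_specs)
    dosages = np.zeros((n, v), dtype=np.float64)
    g_levels = np.arange(3)
    col_of = {s.rsid: j for j, s in enumerate(variant_specs)}
    for j, spec in enumerate(variant_specs):
        if spec.tag_of is not None:
            if spec.tag_of not in col_of:
                raise ValueError(f"variant_specs[{spec.rsid}].tag_of: unknown lead {spec.tag_of!r}")
            lead_col = dosages[:, col_of[spec.tag_of]].copy()
            flip = rng.random(n) < spec.tag_flip
            for stratum in pd.unique(anc):
                maf = spec.stratum_maf(stratum)
                redraw = flip & (anc == stratum)
                lead_col[redraw] = rng.binomial(2, maf, size=int(redraw.sum()))
            dosages[:, j] = lead_col
            continue
        col = np.empty(n, dtype=np.float64)
        for stratum in pd.unique(anc):
            maf = spec.stratum_maf(stratum)
            hwe = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2])
            in_str = anc == stratum
            ctrl = in_str & (subtype < 0)
            col[ctrl] = rng.binomial(2, maf, size=int(ctrl.sum()))
            for k, beta in enumerate(spec.beta_k):
                sel = in_str & (subtype == k)
                m = int(sel.sum())
                if m == 0:
                    continue
                w = hwe * np.exp(beta * g_levels)
                col[sel] = rng.choice(g_levels, size=m, p=w / w.sum())
        dosages[:, j] = col
    variants = pd.DataFrame(
        {
            "rsid": [s.rsid for s in variant_specs],
            "chrom": [s.chrom for s in variant_specs],
            "pos": [s.pos for s in variant_specs],
            "ref": [s.ref for s in variant_specs],
            "alt": [s.alt for s in variant_specs],
            "locus_label": [s.locus_label or s.rsid for s in variant_specs],
        }
    )
    return GenotypeMatrix(subject_ids=ids.copy(), variants=variants, dosages=dosages)


#: code emitted to mark simulated endometriosis cases; bare "N80" matches the
#: case rule but no 4-character anatomical-site prefix.
CASE_MARKER_CODE = ("ICD10", "N80")


def emit_icd_records(
    feature_flags: PhenotypeMatrix,
    catalog: FeatureCatalog,
    icd_sensitivity: float = 1.0,
    seed: int = 0,
    case_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long ICD table from binary feature flags (inverse of extraction).

    Each positive flag emits one code — the feature's first ICD-10 prefix
    (first ICD-9 prefix when no ICD-10 prefix exists) — kept with
    probability ``icd_sensitivity``. Subjects in ``case_ids`` additionally
    emit the endometriosis marker code.
    """
    name_to_entry = {e.feature_name: e for e in catalog.entries}
    missing = [f for f in feature_flags.feature_names if f not in name_to_entry]
    if missing:
        raise KeyError(f"features missing from catalog: {missing}")
    rng = np.random.default_rng(seed)
    rows_s, rows_v, rows_c = [], [], []
    ids = feature_flags.subject_ids
    for j, fname in enumerate(feature_flags.feature_names):
        entry = name_to_entry[fname]
        if entry.icd10_prefixes:
            vocab, code = "ICD10", entry.icd10_prefixes[0]
        else:
            vocab, code = "ICD9", entry.icd9_prefixes[0]
        pos = np.flatnonzero(feature_flags.values[:, j] == 1)
        if icd_sensitivity < 1.0:
            pos = pos[rng.random(len(pos)) < icd_sensitivity]
        rows_s.extend(ids[pos])
        rows_v.extend([vocab] * len(pos))
        rows_c.extend([code] * len(pos))
    if case_ids is not None:
        vocab, code = CASE_MARKER_CODE
        rows_s.extend(case_ids)
        rows_v.extend([vocab] * len(case_ids))
        rows_c.extend([code] * len(case_ids))
    return pd.DataFrame({"subject_id": rows_s, "vocabulary": rows_v, "code": rows_c})


def simulate_cohort(config: SimConfig, seed: int | None = None,
                    catalog: FeatureCatalog | None = None) -> CohortBundle:
    """Generate a full cohort bundle; identical config + seed gives an
    identical bundle."""
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    catalog = catalog or default_catalog()
    p_jk = np.asarray(config.feature_prevalence, dtype=float)
    p_j0 = np.asarray(config.control_feature_prevalence, dtype=float)
    n_feat = p_jk.shape[0]
    if config.feature_names is not None:
        feat_names = list(config.feature_names)
    else:
        non_anat = [e.feature_name for e in catalog.entries if e.group != "anatomical_subtype"]
        if n_feat > len(non_anat):
            raise ValueError("feature_prevalence: more rows than non-anatomical catalog features; pass feature_names")
        feat_names = non_anat[:n_feat]

    n_cases = int(np.sum(config.n_cases_per_subtype))
    n_total = config.n_controls + n_cases
    width = max(6, len(str(n_total)))
    ids = np.array([f"S{i:0{width}d}" for i in range(n_total)], dtype=object)
    subtype = np.full(n_total, -1, dtype=int)
    start = config.n_controls
    for k, c in enumerate(config.n_cases_per_subtype):
        subtype[start:start + c] = k
        start += c

    subjects = pd.DataFrame(
        {
            "subject_id": ids,
            "age": np.round(np.clip(rng.normal(50.0, 13.0, size=n_total), 18, 90), 1),
            "sex": "female",
            "ancestry": _draw_ancestry(rng, config.strata, n_total),
            "dataset": config.dataset,
        }
    )
    truth_subtype = pd.Series(subtype, index=pd.Index(ids, name="subject_id"), name="subtype")

    # binary features: Bernoulli(p_j0) controls, Bernoulli(p_jk) per subtype
    flags = np.zeros((n_total, n_feat), dtype=np.int8)
    ctrl = subtype < 0
    flags[ctrl] = rng.random((int(ctrl.sum()), n_feat)) < p_j0
    for k in range(config.n_subtypes):
        sel = subtype == k
        flags[sel] = rng.random((int(sel.sum()), n_feat)) < p_jk[:, k]
    feature_flags = PhenotypeMatrix(ids.copy(), feat_names, flags)

    icd = emit_icd_records(
        feature_flags, catalog, config.icd_sensitivity,
        seed=int(rng.integers(2 ** 31)), case_ids=list(ids[~ctrl]),
    )
    genotypes = simulate_genotypes(subjects, truth_subtype, config.variant_specs,
                                   seed=int(rng.integers(2 ** 31)))
    truth = SyntheticTruth(
        subtype=truth_subtype,
        variant_betas={s.rsid: tuple(s.beta_k) for s in config.variant_specs},
        feature_prevalence=pd.DataFrame(
            np.column_stack([p_jk, p_j0]), index=feat_names,
            columns=[f"subtype_{k}" for k in range(config.n_subtypes)] + ["control"],
        ),
    )
    return CohortBundle(subjects=subjects, icd=icd, genotypes=genotypes,
                        truth=truth, feature_flags=feature_flags)
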