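"""Binary clinical feature extraction from ICD-coded EHR tables.

Endometriosis case status is defined from structured billing codes alone:
any ICD-9 code with prefix ``617`` or ICD-10 code with prefix ``N80``
(matching is performed on uppercased, dot-stripped canonical codes).
Clinical features are "ever coded" flags: a subject is positive for a
feature if any of her codes matches any of the feature's ICD prefixes,
with no date logic.

The default catalog carries 39 features in four groups — 9 ICD-coded
anatomical lesion sites, 14 comorbidities, 8 symptoms and 8
pregnancy-related phenotypes. The anatomical-site flags are excluded from
clustering and used only for cluster characterization; the remaining
features are additionally filtered on prevalence among cases before
clustering. The catalog is user-overridable via YAML because real sites
differ in coding practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SubjectRecord",
    "CatalogEntry",
    "FeatureCatalog",
    "PhenotypeMatrix",
    "default_catalog",
    "normalize_icd",
    "case_status",
    "extract_features",
    "prevalence_filter",
]

FEATURE_GROUPS = ("anatomical_subtype", "comorbidity", "symptom", "pregnancy")

#: ICD prefixes (canonical form) that define endometriosis case status.
CASE_PREFIXES = {"ICD9": ("617",), "ICD10": ("N80",)}


@dataclass(frozen=True)
class SubjectRecord:
    """One cohort member. ``sex`` is the EHR-recorded sex used for the
    female-only restriction; ``ancestry`` and ``dataset`` define the
    association strata."""

    subject_id: str
    age: float
    sex: str  # "female" | "male" | "other"
    ancestry: str  # e.g. "AFR", "EUR"
    dataset: str


@dataclass(frozen=True)
class CatalogEntry:
    feature_name: str
    group: str
    icd9_prefixes: tuple[str, ...]
    icd10_prefixes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.group not in FEATURE_GROUPS:
            raise ValueError(f"unknown feature group {self.group!r}")
        if not (self.icd9_prefixes or self.icd10_prefixes):
            raise ValueError(f"feature {self.feature_name!r} has no ICD prefixes")


@dataclass
class FeatureCatalog:
    """Ordered list of feature definitions; prefix matching is on
    canonical (uppercase, dot-stripped) codes."""

    entries: list[CatalogEntry] = field(default_factory=list)

    @property
    def feature_names(self) -> list[str]:
        return [e.feature_name for e in self.entries]

    def groups(self) -> dict[str, str]:
        return {e.feature_name: e.group for e in self.entries}

    def entry(self, feature_name: str) -> CatalogEntry:
        for e in self.entries:
            if e.feature_name == feature_name:
                return e
        raise KeyError(f"feature {feature_name!r} not in catalog")

    def group_counts(self) -> dict[str, int]:
        counts = {g: 0 for g in FEATURE_GROUPS}
        for e in self.entries:
            counts[e.group] += 1
        return counts

    # -- YAML round trip -------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = [
            {
                "feature_name": e.feature_name,
                "group": e.group,
                "icd9_prefixes": list(e.icd9_prefixes),
                "icd10_prefixes": list(e.icd10_prefixes),
            }
            for e in self.entries
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FeatureCatalog":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        entries = [
            CatalogEntry(
                feature_name=item["feature_name"],
                group=item["group"],
                icd9_prefixes=tuple(item.get("icd9_prefixes") or ()),
                icd10_prefixes=tuple(item.get("icd10_prefixes") or ()),
            )
            for item in payload
        ]
        return cls(entries)


@dataclass
class PhenotypeMatrix:
    """Subjects x binary clinical features."""

    subject_ids: np.ndarray  # shape (n,), dtype object/str
    feature_names: list[str]
    values: np.ndarray  # shape (n, p), {0, 1}

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids)
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ValueError("shape mismatch between ids, names and values")
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            raise ValueError("phenotype matrix entries must be 0/1")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.subject_ids, name="subject_id"),
            columns=self.feature_names,
        )

    def select_features(self, names: Sequence[str]) -> "PhenotypeMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return PhenotypeMatrix(self.subject_ids, list(names), self.values[:, idx])

    def select_subjects(self, mask_or_ids) -> "PhenotypeMatrix":
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            mask = arr
        else:
            mask = np.isin(self.subject_ids, arr)
        return PhenotypeMatrix(self.subject_ids[mask], list(self.feature_names),
                               self.values[mask])

    def reindex_subjects(self, ids: Sequence[str]) -> "PhenotypeMatrix":
        """Rows in the order of ``ids``; subjects without a row get zeros
        (never-coded semantics)."""
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        out = np.zeros((len(ids), len(self.feature_names)), dtype=np.int8)
        for j, s in enumerate(ids):
            i = pos.get(s)
            if i is not None:
                out[j] = self.values[i]
        return PhenotypeMatrix(np.asarray(ids), list(self.feature_names), out)


# ---------------------------------------------------------------------------
# Default 39-feature catalog: 9 anatomical sites / 14 comorbidities /
# 8 symptoms / 8 pregnancy phenotypes. Prefixes are canonical (no dots).
# ---------------------------------------------------------------------------

_DEFAULT_ENTRIES: list[tuple[str, str, tuple[str, ...], tuple[str, ...]]] = [
    # anatomical lesion sites (ICD-9 617.x / ICD-10 N80.x)
    ("endometriosis_uterus", "anatomical_subtype", ("6170",), ("N800",)),
    ("endometriosis_ovary", "anatomical_subtype", ("6171",), ("N801",)),
    ("endometriosis_fallopian_tube", "anatomical_subtype", ("6172",), ("N802",)),
    ("endometriosis_peritoneum", "anatomical_subtype", ("6173",), ("N803",)),
    ("endometriosis_rectovaginal", "anatomical_subtype", ("6174",), ("N804",)),
    ("endometriosis_intestine", "anatomical_subtype", ("6175",), ("N805",)),
    ("endometriosis_cutaneous_scar", "anatomical_subtype", ("6176",), ("N806",)),
    ("endometriosis_other_site", "anatomical_subtype", ("6178",), ("N808",)),
    ("endometriosis_unspecified", "anatomical_subtype", ("6179",), ("N809",)),
    # comorbidities
    ("migraine", "comorbidity", ("346",), ("G43",)),
    ("irritable_bowel_syndrome", "comorbidity", ("5641",), ("K58",)),
    ("fibromyalgia", "comorbidity", ("7291",), ("M797",)),
    ("asthma", "comorbidity", ("493",), ("J45",)),
    ("interstitial_cystitis", "comorbidity", ("5951",), ("N301",)),
    ("hypertension", "comorbidity", ("401",), ("I10",)),
    ("abnormal_cholesterol", "comorbidity", ("272",), ("E78",)),
    ("leiomyoma_uterus", "comorbidity", ("218",), ("D25",)),
    ("ovarian_cyst", "comorbidity", ("6202",), ("N832",)),
    ("anxiety", "comorbidity", ("3000",), ("F41",)),
    ("depression", "comorbidity", ("311",), ("F32", "F33")),
    ("pelvic_inflammatory_disease", "comorbidity", ("614",), ("N73",)),
    ("type2_diabetes", "comorbidity", ("2500",), ("E11",)),
    ("obesity", "comorbidity", ("278",), ("E66",)),
    # symptoms
    ("dysmenorrhea", "symptom", ("6253",), ("N946",)),
    ("dysuria", "symptom", ("7881",), ("R30",)),
    ("pelvic_pain", "symptom", ("6259",), ("R102",)),
    ("lower_abdominal_pain", "symptom", ("78903",), ("R103",)),
    ("shortness_of_breath", "symptom", ("78605",), ("R0602",)),
    ("dyspareunia", "symptom", ("6250",), ("N941",)),
    ("heavy_menstrual_bleeding", "symptom", ("6262",), ("N920",)),
    ("irregular_menstruation", "symptom", ("6264",), ("N924", "N926")),
    # pregnancy-related phenotypes
    ("infertility", "pregnancy", ("628",), ("N97",)),
    ("high_risk_pregnancy_supervision", "pregnancy", ("V23",), ("O09",)),
    ("spontaneous_abortion", "pregnancy", ("634",), ("O03",)),
    ("ectopic_pregnancy", "pregnancy", ("633",), ("O00",)),
    ("preeclampsia", "pregnancy", ("6424",), ("O14",)),
    ("gestational_diabetes", "pregnancy", ("6488",), ("O244",)),
    ("preterm_delivery", "pregnancy", ("6442",), ("O601",)),
    ("cesarean_delivery", "pregnancy", ("6697",), ("O82",)),
]


def default_catalog() -> FeatureCatalog:
    """Built-in 39-entry catalog (9/14/8/8 per group).

    ICD prefixes are plausible defaults for the named conditions; sites
    with different coding practice should supply their own YAML catalog.
    """
    return FeatureCatalog([CatalogEntry(n, g, i9, i10) for n, g, i9, i10 in _DEFAULT_ENTRIES])


# ---------------------------------------------------------------------------
# ICD handling
# ---------------------------------------------------------------------------

def normalize_icd(code: str, vocabulary: str | None = None) -> str:
    """Canonical form: uppercase, dots stripped. ``"n80.1" -> "N801"``."""
    if code is None or str(code).strip() == "":
        raise ValueError("empty ICD code")
    return str(code).strip().upper().replace(".", "")


def _normalized_codes(records: pd.DataFrame) -> pd.DataFrame:
    req = {"subject_id", "vocabulary", "code"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"ICD table missing columns: {sorted(missing)}")
    bad_vocab = set(records["vocabulary"].unique()) - {"ICD9", "ICD10"}
    if bad_vocab:
        raise ValueError(f"unknown vocabulary values: {sorted(bad_vocab)}")
    out = records.copy()
    if out["code"].astype(str).str.strip().eq("").any():
        raise ValueError("empty ICD code in records")
    out["code"] = out["code"].astype(str).str.strip().str.upper().str.replace(".", "", regex=False)
    return out


def case_status(records: pd.DataFrame, subjects: pd.DataFrame) -> pd.Series:
    """Endometriosis case/control status per female subject.

    A subject is a case iff she carries any ICD-9 code with prefix 617 or
    ICD-10 code with prefix N80; every other female is a control. Male /
    other subjects are excluded from the returned series.

    Parameters
    ----------
    records : long table with columns subject_id, vocabulary, code
    subjects : table with columns subject_id, sex

    Returns
    -------
    pandas.Series indexed by subject_id with values "case"/"control",
    covering exactly the female subjects.
    """
    recs = _normalized_codes(records)
    females = subjects.loc[subjects["sex"] == "female", "subject_id"]
    case_ids: set[str] = set()
    for vocab, prefixes in CASE_PREFIXES.items():
        sub = recs[recs["vocabulary"] == vocab]
        for pre in prefixes:
            case_ids.update(sub.loc[sub["code"].str.startswith(pre), "subject_id"])
    status = pd.Series(
        ["case" if s in case_ids else "control" for s in females],
        index=pd.Index(females.to_numpy(), name="subject_id"),
        name="status",
    )
    return status


def extract_features(
    records: pd.DataFrame,
    catalog: FeatureCatalog,
    subject_ids: Sequence[str] | None = None,
) -> PhenotypeMatrix:
    """Ever-coded binary feature matrix.

    Entry (i, j) is 1 iff subject i ever has a code whose canonical form
    starts with one of feature j's prefixes (in the matching vocabulary).
    ``subject_ids`` fixes the row universe and order; subjects with no
    matching codes get all-zero rows. When omitted, rows are the distinct
    subjects present in ``records`` in order of first appearance.
    """
    recs = _normalized_codes(records)
    if subject_ids is None:
        subject_ids = list(dict.fromkeys(recs["subject_id"]))
    subject_ids = list(subject_ids)
    pos = {s: i for i, s in enumerate(subject_ids)}
    values = np.zeros((len(subject_ids), len(catalog.entries)), dtype=np.int8)
    for vocab, attr in (("ICD9", "icd9_prefixes"), ("ICD10", "icd10_prefixes")):
        sub = recs[recs["vocabulary"] == vocab]
        if sub.empty:
            continue
        codes = sub["code"].to_numpy()
        sids = sub["subject_id"].to_numpy()
        keep = np.array([s in pos for s in sids])
        codes, sids = codes[keep], sids[keep]
        rows = np.array([pos[s] for s in sids], dtype=int) if len(sids) else np.empty(0, int)
        for j, entry in enumerate(catalog.entries):
            prefixes = getattr(entry, attr)
            if not prefixes or len(codes) == 0:
                continue
            hit = np.zeros(len(codes), dtype=bool)
            for pre in prefixes:
                hit |= np.char.startswith(codes.astype(str), pre)
            if hit.any():
                values[rows[hit], j] = 1
    return PhenotypeMatrix(np.asarray(subject_ids), catalog.feature_names, values)


def prevalence_filter(
    matrix: PhenotypeMatrix,
    case_flags: np.ndarray,
    catalog: FeatureCatalog,
    min_prevalence: float = 0.05,
    drop_groups: Iterable[str] = ("anatomical_subtype",),
) -> PhenotypeMatrix:
    """Select clustering features: drop anatomical-site columns, then keep
    features whose prevalence among cases is >= ``min_prevalence`` (closed
    threshold). Column order is preserved.
    """
    if not 0 <= min_prevalence <= 1:
        raise ValueError("min_prevalence must be in [0, 1]")
    case_flags = np.asarray(case_flags, dtype=bool)
    if case_flags.shape[0] != matrix.n_subjects:
        raise ValueError("case_flags length mismatch")
    n_cases = int(case_flags.sum())
    if n_cases == 0:
        raise ValueError("prevalence undefined: zero cases")
    groups = catalog.groups()
    drop = set(drop_groups)
    keep_names = []
    for j, name in enumerate(matrix.feature_names):
        if groups.get(name) in drop:
            continue
        prev = matrix.values[case_flags, j].mean()
        if prev >= min_prevalence:
            keep_names.append(name)
    return matrix.select_features(keep_names)
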