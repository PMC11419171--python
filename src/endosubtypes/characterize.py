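"""Cluster characterization by feature-enrichment testing.

Each cluster is compared against the union of the other clusters with a
pooled two-population z-score proportion test per binary feature. The
squared z-statistic equals the Pearson chi-square of the implied 2x2
table, an identity the test suite uses as the oracle. Chart-review-style
variables enter as extra binary flags through the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import PhenotypeMatrix

__all__ = ["ProportionTestResult", "proportion_z_test", "enrichment_table"]


@dataclass
class ProportionTestResult:
    feature: str
    cluster: int
    x_in: int
    n_in: int
    x_out: int
    n_out: int
    z: float
    p: float
    significant: bool
    degenerate: bool

    @property
    def prevalence_in(self) -> float:
        return self.x_in / self.n_in if self.n_in else float("nan")

    @property
    def prevalence_out(self) -> float:
        return self.x_out / self.n_out if self.n_out else float("nan")


def proportion_z_test(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled
    proportion; the two-sided p-value is from the standard normal.
    Degenerate tables (pooled proportion 0 or 1) return (nan, nan) — the
    caller flags them rather than reporting a silent zero.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both sample sizes must be >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return float("nan"), float("nan")
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def enrichment_table(
    features: PhenotypeMatrix,
    labels,
    extra_flags: PhenotypeMatrix | None = None,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Cluster-vs-rest proportion tests for every (feature, cluster).

    Significance is Bonferroni-corrected over all emitted tests by
    default (``correction="none"`` disables it). Rows for empty clusters
    or all-0/all-1 features are flagged ``degenerate`` with NaN z/p.
    """
    labels = np.asarray(labels)
    if len(labels) != features.n_subjects:
        raise ValueError("labels length mismatch")
    clusters = np.unique(labels[labels != -1])
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters for cluster-vs-rest testing")
    mats = [features]
    if extra_flags is not None:
        if extra_flags.n_subjects != features.n_subjects:
            raise ValueError("extra_flags subject count mismatch")
        mats.append(extra_flags)

    rows = []
    for mat in mats:
        V = mat.values
        for j, fname in enumerate(mat.feature_names):
            col = V[:, j]
            for c in clusters:
                inside = labels == c
                outside = (labels != c) & (labels != -1)
                n_in, n_out = int(inside.sum()), int(outside.sum())
                x_in, x_out = int(col[inside].sum()), int(col[outside].sum())
                if n_in == 0 or n_out == 0:
                    z = p = float("nan")
                else:
                    z, p = proportion_z_test(x_in, n_in, x_out, n_out)
                rows.append((fname, int(c), x_in, n_in, x_out, n_out,
                             x_in / n_in if n_in else np.nan,
                             x_out / n_out if n_out else np.nan, z, p))
    out = pd.DataFrame(
        rows, columns=["feature", "cluster", "x_in", "n_in", "x_out", "n_out",
                       "prevalence_in", "prevalence_out", "z", "p"],
    )
    out["degenerate"] = out["p"].isna()
    n_tests = len(out)
    if correction == "bonferroni":
        threshold = alpha / n_tests
    elif correction == "none":
        threshold = alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    out["significant"] = out["p"] < threshold
    out.attrs["alpha"] = alpha
    out.attrs["n_tests"] = n_tests
    out.attrs["threshold"] = threshold
    return out
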