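"""Per-variant differential carrier-frequency testing between cohorts.

Each variant yields a 2x2 table of carriers vs non-carriers in the AAM and
CM cohorts, tested with Fisher's exact test (two-sided, point-probability
summation). P-values are adjusted with the Benjamini-Hochberg step-up over
all variants tested in the run; variants with q below alpha are flagged
significant and assigned a dominant cohort (the one with the higher
carrier proportion; exact ties get dominance "none" and are excluded from
downstream ancestry classification).

The two-sided Fisher p sums the probabilities of all tables (at the
observed margins) whose point probability does not exceed the observed
table's, with a 1e-7 relative tolerance so that floating-point ties count
as ties. scipy's implementation uses the same convention and serves as an
independent cross-check in the test suite, not as the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .variants import (
    AnnotatedVariant,
    CohortVariantMatrix,
    KARYOTYPE_ORDER,
    VariantKey,
)

_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class VariantTestResult:
    """One variant's 2x2 test: counts, odds ratio, p, q, significance, dominance.

    a/b: AAM carriers / non-carriers; c/d: CM carriers / non-carriers.
    """

    key: VariantKey
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    q: float
    significant: bool
    dominant: str  # "AAM" | "CM" | "none"


@lru_cache(maxsize=1 << 16)
def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Fisher's exact test on [[a, b], [c, d]]: (odds ratio, two-sided p).

    Odds ratio is the sample ad/bc with the 0/inf conventions (0/0 -> nan).
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValidationError(f"cell counts must be non-negative integers, got {x}")
    n = a + b + c + d
    if n == 0:
        raise ValidationError("undefined test: all-zero 2x2 table")
    row1, col1 = a + b, a + c
    # hypergeometric support for the top-left cell at fixed margins
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    pmf = stats.hypergeom.pmf(np.arange(lo, hi + 1), n, row1, col1)
    observed = pmf[a - lo]
    p = float(pmf[pmf <= observed * (1.0 + _TIE_RTOL)].sum())
    p = min(1.0, p)
    if b * c == 0:
        odds = np.nan if a * d == 0 else np.inf
    else:
        odds = a * d / (b * c)
    return float(odds), p


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order-preserving.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def test_all_variants(
    matrix: CohortVariantMatrix, alpha: float = 0.05
) -> list[VariantTestResult]:
    """Fisher-test every variant in the matrix with one genome-wide BH pass."""
    sizes = matrix.cohort_sizes
    n_aam, n_cm = sizes["AAM"], sizes["CM"]
    if n_aam == 0 or n_cm == 0:
        raise ValidationError("matrix must contain two non-empty cohorts")
    a_counts = matrix.carrier_counts("AAM")
    c_counts = matrix.carrier_counts("CM")
    raw = [
        fisher_exact_2x2(int(a), n_aam - int(a), int(c), n_cm - int(c))
        for a, c in zip(a_counts, c_counts)
    ]
    p_values = np.array([p for _, p in raw])
    q_values = benjamini_hochberg(p_values) if len(p_values) else np.array([])
    results = []
    for key, a, c, (odds, p), q in zip(matrix.variants, a_counts, c_counts, raw, q_values):
        a, c = int(a), int(c)
        significant = bool(q < alpha)
        if not significant or a / n_aam == c / n_cm:
            dominant = "none"
        else:
            dominant = "AAM" if a / n_aam > c / n_cm else "CM"
        results.append(
            VariantTestResult(key, a, n_aam - a, c, n_cm - c, odds, float(p), float(q),
                              significant, dominant)
        )
    return results


def results_to_frame(
    results: list[VariantTestResult],
    annotations: dict[VariantKey, AnnotatedVariant] | None = None,
) -> pd.DataFrame:
    ann = annotations or {}
    return pd.DataFrame(
        {
            "chrom": [r.key.contig for r in results],
            "pos": [r.key.pos for r in results],
            "ref": [r.key.ref for r in results],
            "alt": [r.key.alt for r in results],
            "gene": [ann[r.key].gene if r.key in ann else "" for r in results],
            "aam_carriers": [r.a for r in results],
            "aam_noncarriers": [r.b for r in results],
            "cm_carriers": [r.c for r in results],
            "cm_noncarriers": [r.d for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "significant": [r.significant for r in results],
            "dominant": [r.dominant for r in results],
        }
    )


def consequence_proportions(
    annotations: dict[VariantKey, AnnotatedVariant],
    variant_sets: dict[str, list[VariantKey]],
) -> tuple[pd.DataFrame, float]:
    """Consequence-category proportions per variant set + homogeneity p.

    Empty sets are excluded (with a proportions row absent); the Pearson
    chi-square homogeneity test runs across the remaining sets after
    dropping categories that are zero everywhere. Returns (long-format
    proportions frame, p). p is nan when fewer than two non-empty sets or
    fewer than two categories remain.
    """
    rows = []
    counts: dict[str, dict[str, int]] = {}
    for set_name, keys in variant_sets.items():
        if not keys:
            continue
        tally: dict[str, int] = {}
        for k in keys:
            cons = annotations[k].consequence if k in annotations else "unannotated"
            tally[cons] = tally.get(cons, 0) + 1
        counts[set_name] = tally
        total = sum(tally.values())
        for cons, n in sorted(tally.items()):
            rows.append({"set": set_name, "consequence": cons, "count": n,
                         "proportion": n / total})
    frame = pd.DataFrame(rows)
    if len(counts) < 2:
        return frame, float("nan")
    categories = sorted({c for t in counts.values() for c in t})
    table = np.array(
        [[t.get(c, 0) for c in categories] for t in counts.values()], dtype=float
    )
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        return frame, float("nan")
    if np.array_equal(table, np.tile(table[0], (table.shape[0], 1))):
        # identical rows: chi2 = 0 exactly, avoid scipy's low-count warnings
        return frame, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return frame, float(p)


def chromosome_distribution(
    results: list[VariantTestResult],
) -> pd.DataFrame:
    """Per-contig variant counts (all and significant), karyotype order.

    Contigs outside the standard karyotype (chr1..chr22, chrX, chrY) are
    appended after it in name order.
    """
    all_counts: dict[str, int] = {c: 0 for c in KARYOTYPE_ORDER}
    sig_counts: dict[str, int] = {c: 0 for c in KARYOTYPE_ORDER}
    extras = set()
    for r in results:
        contig = r.key.contig
        if contig not in all_counts:
            extras.add(contig)
            all_counts[contig] = 0
            sig_counts[contig] = 0
        all_counts[contig] += 1
        if r.significant:
            sig_counts[contig] += 1
    order = list(KARYOTYPE_ORDER) + sorted(extras)
    return pd.DataFrame(
        {"contig": order,
         "n_variants": [all_counts[c] for c in order],
         "n_significant": [sig_counts[c] for c in order]}
    )
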