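"""Offline hypergeometric over-representation analysis against GMT gene sets.

Standard GMT dialect: one set per line, tab-separated as
``name<TAB>description<TAB>gene1<TAB>gene2...``. The test is the upper
tail of the hypergeometric distribution — the probability of drawing at
least the observed overlap when ``query_size`` genes are sampled without
replacement from a background universe containing ``set_size`` members of
the set — with Benjamini-Hochberg adjustment across all sets in the
collection (separate collections, e.g. GO vs Hallmark, are corrected
separately by running them separately).

The background defaults to an integer universe size of 20,000 (a
conventional count of human protein-coding genes); supplying an explicit
background gene list overrides it, in which case the query is first
intersected with the background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .errors import FormatError, ValidationError
from .diff import benjamini_hochberg

DEFAULT_BACKGROUND_SIZE = 20_000


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe (list or bare size)."""

    sets: dict[str, tuple[str, frozenset[str]]]  # name -> (description, members)
    background: frozenset[str] | int = DEFAULT_BACKGROUND_SIZE

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
        if isinstance(self.background, int):
            if self.background < 1:
                raise ValidationError("background size must be positive")
        else:
            self.background = frozenset(g.upper() for g in self.background)
            for name, (_, members) in self.sets.items():
                if not members <= self.background:
                    raise ValidationError(
                        f"gene set {name!r} has members outside the background"
                    )

    @property
    def background_size(self) -> int:
        return self.background if isinstance(self.background, int) else len(self.background)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    background_size: int
    p: float
    q: float


def read_gmt(path: str | Path, background: frozenset[str] | int = DEFAULT_BACKGROUND_SIZE) -> GeneSetCollection:
    """Parse a GMT file; duplicate members within a set are deduplicated."""
    text = Path(path).read_text()
    if not text.strip():
        raise FormatError(f"empty GMT file: {path}")
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, description = fields[0], fields[1]
        members = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
        if not members:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
        sets[name] = (description, members)
    return GeneSetCollection(sets, background)


def hypergeometric_enrichment(
    query_genes: Iterable[str], collection: GeneSetCollection
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test of the query against every set.

    The query is uppercased, deduplicated, and — when the background is a
    gene list — intersected with it. Results are sorted by (q, p, name).
    An empty post-intersection query yields an empty result list with a
    warning.
    """
    query = {str(g).strip().upper() for g in query_genes if str(g).strip()}
    bg = collection.background
    if not isinstance(bg, int):
        query &= bg
    if not query:
        warnings.warn("query is empty after background intersection", stacklevel=2)
        return []
    m = collection.background_size
    n_query = len(query)
    if n_query > m:
        raise ValidationError(
            f"query size {n_query} exceeds background size {m}; "
            "supply an explicit background list or a larger universe"
        )
    names, p_values, overlaps = [], [], []
    for name, (_, members) in collection.sets.items():
        k = len(query & members)
        # P(X >= k) for X ~ Hypergeom(M=m, n=len(members), N=n_query)
        p = float(stats.hypergeom.sf(k - 1, m, len(members), n_query))
        names.append(name)
        overlaps.append(k)
        p_values.append(min(1.0, p))
    q_values = benjamini_hochberg(p_values)
    results = [
        EnrichmentResult(name, k, len(collection.sets[name][1]), n_query, m, p, float(q))
        for name, k, p, q in zip(names, overlaps, p_values, q_values)
    ]
    results.sort(key=lambda r: (r.q, r.p, r.set_name))
    return results


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "overlap": [r.overlap for r in results],
            "set_size": [r.set_size for r in results],
            "query_size": [r.query_size for r in results],
            "background_size": [r.background_size for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
        }
    )


def read_query_genes(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line query gene list."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
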