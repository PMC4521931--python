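"""Term over-representation analysis with Fisher's exact test and EASE.

A regulated-protein list is tested term by term against a background
universe.  With N background proteins, K annotated to a term, and a list
of n proteins of which k carry the term, the one-tailed Fisher p-value is
the hypergeometric upper tail P(X >= k).  The EASE score is the same tail
after discounting one overlapping protein (jackknife: P(X >= k-1)), which
penalizes terms supported by a single gene.  A term passes under the
standard filters k >= 2 and EASE < 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationTable",
    "fisher_one_tailed",
    "ease_score",
    "enrich",
]


class ContainmentError(ValueError):
    """Protein list is not contained in the declared background."""


@dataclass
class AnnotationTable:
    """Flat term -> protein-accession mapping with optional metadata."""

    terms: dict[str, set[str]]
    labels: dict[str, str] = field(default_factory=dict)
    namespaces: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, members in self.terms.items():
            if not members:
                raise ValueError(f"term {term!r} has an empty member set")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AnnotationTable":
        """Build from a long table with ``accession``/``term_id`` columns."""
        terms: dict[str, set[str]] = {}
        for acc, term in zip(df["accession"], df["term_id"]):
            terms.setdefault(str(term), set()).add(str(acc))
        labels = {}
        namespaces = {}
        if "term_label" in df.columns:
            labels = dict(zip(df["term_id"].astype(str), df["term_label"].astype(str)))
        if "namespace" in df.columns:
            namespaces = dict(zip(df["term_id"].astype(str), df["namespace"].astype(str)))
        return cls(terms, labels, namespaces)

    def restricted_to(self, background: set[str]) -> "AnnotationTable":
        """Drop accessions outside ``background`` and empty terms."""
        terms = {
            t: m & background for t, m in self.terms.items() if m & background
        }
        return AnnotationTable(terms, self.labels, self.namespaces)


def _check_margins(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent margins k={k}, K={K}, n={n}, N={N}")


def fisher_one_tailed(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k), X ~ Hypergeom(N, K, n): over-representation tail."""
    _check_margins(k, K, n, N)
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def ease_score(k: int, K: int, n: int, N: int) -> float:
    """Jackknifed Fisher tail: P(X >= k-1); 1.0 for single-gene overlaps."""
    _check_margins(k, K, n, N)
    return fisher_one_tailed(max(k - 1, 0), K, n, N)


def enrich(
    protein_list: set[str],
    background: set[str],
    annotations: AnnotationTable,
    min_count: int = 2,
    ease_threshold: float = 0.1,
) -> pd.DataFrame:
    """Rank annotation terms by EASE score over a protein list.

    Returns one row per term overlapping the list (k >= 1) with columns
    ``term, k, K, n, N, fisher_p, ease_p, ease_bh, passes``, sorted by
    ascending EASE, ties broken by descending overlap then term id.
    ``passes`` applies the count and raw-EASE filters; the BH column is
    informational.
    """
    protein_list = set(protein_list)
    background = set(background)
    if not background:
        raise ValueError("background must be non-empty")
    if not protein_list <= background:
        missing = sorted(protein_list - background)[:5]
        raise ContainmentError(
            f"{len(protein_list - background)} list proteins absent from "
            f"background (e.g. {missing})"
        )
    if not 0 < ease_threshold <= 1:
        raise ValueError("ease_threshold must be in (0, 1]")

    ann = annotations.restricted_to(background)
    N, n = len(background), len(protein_list)
    rows = []
    for term, members in ann.terms.items():
        k = len(members & protein_list)
        if k == 0:
            continue
        K = len(members)
        rows.append(
            {
                "term": term,
                "label": ann.labels.get(term, ""),
                "namespace": ann.namespaces.get(term, ""),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "fisher_p": fisher_one_tailed(k, K, n, N),
                "ease_p": ease_score(k, K, n, N),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "term", "label", "namespace", "k", "K", "n", "N",
                "fisher_p", "ease_p", "ease_bh", "passes",
            ]
        )
    out = pd.DataFrame(rows)
    out["ease_bh"] = multipletests(out["ease_p"], method="fdr_bh")[1]
    out["passes"] = (out["k"] >= min_count) & (out["ease_p"] < ease_threshold)
    out = out.sort_values(
        ["ease_p", "k", "term"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return out
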