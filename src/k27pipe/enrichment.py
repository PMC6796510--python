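"""Flat-set functional term enrichment: one-sided hypergeometric test with
Benjamini-Hochberg control at 1% FDR.  Terms are plain gene sets; no
ontology-graph propagation is performed.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .differential import bh_qvalues


@dataclass(frozen=True)
class TermAssignment:
    term_id: str
    term_label: str
    members: frozenset[str]


def term_enrichment(
    study: set[str],
    population: set[str],
    terms: Sequence[TermAssignment] | Mapping[str, Iterable[str]],
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Over-representation of each term in ``study`` against ``population``.

    For a term with K members in a population of N and a study set of n genes
    of which k are in the term, p = P(X >= k) under Hypergeometric(N, K, n).
    Enriched iff BH q-value < ``fdr``.
    """
    if not population:
        raise ValueError("empty population")
    stray = study - population
    if stray:
        raise ValueError(f"study genes absent from population: {sorted(stray)[:10]}")
    if isinstance(terms, Mapping):
        terms = [TermAssignment(t, t, frozenset(m)) for t, m in terms.items()]
    n, N = len(study), len(population)
    rows = []
    for t in terms:
        members = set(t.members) & population
        K = len(members)
        k = len(study & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((t.term_id, t.term_label, k, n, K, N, p))
    df = pd.DataFrame(
        rows, columns=["term_id", "term_label", "k", "n", "K", "N", "p_value"]
    )
    df["q_value"] = bh_qvalues(df["p_value"]) if len(df) else []
    df["enriched"] = df["q_value"] < fdr
    return df.set_index("term_id")
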