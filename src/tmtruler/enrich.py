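"""Gene-set overrepresentation analysis (ORA) and signature overlaps.

ORA asks whether a hit list (e.g. proteins significantly up in one
population) overlaps a named gene set more than chance, given a background
universe.  The test is the one-sided hypergeometric upper tail

    p = P(X >= k),  X ~ Hypergeom(N = |background|,
                                  K = |set ∩ background|,
                                  n = |hits|)

which equals one-sided Fisher's exact test on the 2x2 table.  Multiple sets
are corrected with Benjamini-Hochberg FDR.  The background convention is the
union of proteins detected in either of the two contrasted populations; hits
outside the background are dropped with a warning and gene sets are
intersected with the background before testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "SignatureOverlap",
    "overrepresentation",
    "exhaustion_enrichment",
    "signature_overlap",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets with optional descriptions (GMT-style)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        sets: dict[str, set[str]] = {}
        desc: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (need name, description, >= 1 member): {line!r}")
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate set name in GMT: {name!r}")
            members = {g for g in parts[2:] if g}
            sets[name] = members
            desc[name] = parts[1]
        return cls(sets=sets, descriptions=desc)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                desc = self.descriptions.get(name, "")
                fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


@dataclass(frozen=True)
class SignatureOverlap:
    """Exact partition of two identifier sets (Venn-diagram counts)."""

    a_only: frozenset
    b_only: frozenset
    shared: frozenset

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.a_only), len(self.b_only), len(self.shared)


def hypergeom_upper_tail(overlap: int, background: int, set_size: int, hits: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(N=background, K=set_size, n=hits)."""
    return float(stats.hypergeom.sf(overlap - 1, background, set_size, hits))


def overrepresentation(
    hits,
    background,
    collection: GeneSetCollection,
    min_set: int = 1,
    max_set: int | None = None,
) -> pd.DataFrame:
    """One-sided hypergeometric ORA of a hit list against a collection.

    Returns one row per tested set (term, set_size, background_size,
    n_hits, overlap, fold_enrichment, p_value, fdr, members), sorted by p.
    Set sizes are counted after intersection with the background; sets
    outside [min_set, max_set] are skipped.
    """
    background = set(background)
    hits = set(hits)
    if not background:
        raise ValueError("empty background")
    if not hits:
        raise ValueError("empty hit list")
    outside = hits - background
    if outside:
        logger.warning("overrepresentation: dropping %d hit(s) outside the background", len(outside))
        hits = hits & background
        if not hits:
            raise ValueError("no hits remain inside the background")
    N, n = len(background), len(hits)
    rows = []
    for name, members in collection.sets.items():
        inset = members & background
        K = len(inset)
        if K < min_set or (max_set is not None and K > max_set):
            continue
        k = len(inset & hits)
        fold = (k / n) / (K / N) if K else np.nan
        p = hypergeom_upper_tail(k, N, K, n)
        rows.append((name, K, N, n, k, fold, p, ",".join(sorted(inset & hits))))
    if not rows:
        logger.warning("overrepresentation: no gene set within the size limits")
        return pd.DataFrame(
            columns=["term", "set_size", "background_size", "n_hits", "overlap",
                     "fold_enrichment", "p_value", "fdr", "members"]
        )
    out = pd.DataFrame(
        rows,
        columns=["term", "set_size", "background_size", "n_hits", "overlap",
                 "fold_enrichment", "p_value", "members"],
    )
    out["fdr"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    out = out[["term", "set_size", "background_size", "n_hits", "overlap",
               "fold_enrichment", "p_value", "fdr", "members"]]
    return out.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)


def exhaustion_enrichment(
    up_hits,
    down_hits,
    collection: GeneSetCollection,
    background,
    up_set: str = "exhaustion_up",
    down_set: str = "exhaustion_down",
) -> pd.DataFrame:
    """ORA of a contrast's up/down candidates against an exhaustion signature.

    ``collection`` must provide one set of proteins up-regulated during T
    cell exhaustion and one of down-regulated proteins (names given by
    ``up_set``/``down_set``).  Each non-empty hit direction is tested
    against both signature directions; rows carry a ``hits_direction``
    column.  Empty hit sets are skipped with a warning.
    """
    for required in (up_set, down_set):
        if required not in collection:
            raise ValueError(f"exhaustion collection missing direction set {required!r}")
    sub = GeneSetCollection(
        sets={up_set: collection[up_set], down_set: collection[down_set]},
        descriptions=collection.descriptions,
    )
    frames = []
    for direction, hits in (("up", up_hits), ("down", down_hits)):
        if not set(hits):
            logger.warning("exhaustion_enrichment: empty %s hit set, skipped", direction)
            continue
        res = overrepresentation(hits, background, sub)
        res.insert(0, "hits_direction", direction)
        frames.append(res)
    if not frames:
        return pd.DataFrame(
            columns=["hits_direction", "term", "set_size", "background_size", "n_hits",
                     "overlap", "fold_enrichment", "p_value", "fdr", "members"]
        )
    return pd.concat(frames, ignore_index=True)


def signature_overlap(set_a, set_b) -> SignatureOverlap:
    """Partition two identifier sets into a-only / b-only / shared."""
    a, b = set(set_a), set(set_b)
    return SignatureOverlap(
        a_only=frozenset(a - b), b_only=frozenset(b - a), shared=frozenset(a & b)
    )
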