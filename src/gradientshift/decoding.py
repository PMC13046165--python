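"""Meta-analytic term-map decoding.

Correlates an input brain map with each map of a term set over the shared
analysis mask and ranks the terms by descending Pearson r (ties broken
lexicographically by term name).  Non-cognitive/anatomical terms can be
excluded case-insensitively; the default exclusion set is ('stimulation',
'method', 'cortex', 'gyrus').  Real term maps, when available, are read from
a directory of NIfTI volumes with a (term,path) manifest CSV; the package
ships only the decoding engine plus synthetic fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import AnalysisMask, load_volume, vectorize
from .simulate import TermMapSet

__all__ = ["DEFAULT_EXCLUSIONS", "DecodingResult", "decode_map",
           "load_term_maps"]

DEFAULT_EXCLUSIONS: tuple[str, ...] = ("stimulation", "method", "cortex", "gyrus")


@dataclass
class DecodingResult:
    """Ranked term correlations for one input map."""

    table: pd.DataFrame          # term, r, rank (rank 1 = highest r)
    excluded_terms: list[str]

    @property
    def top_term(self) -> str:
        return str(self.table.iloc[0]["term"])


def decode_map(
    input_map: np.ndarray,
    terms: TermMapSet,
    exclusions: Iterable[str] = DEFAULT_EXCLUSIONS,
) -> DecodingResult:
    """Pearson r of the input map with every retained term map, ranked."""
    x = np.asarray(input_map, dtype=np.float64)
    if x.size != terms.maps.shape[0]:
        raise ValueError("input map and term maps do not share the mask")
    xc = x - x.mean()
    xn = np.sqrt(xc @ xc)
    if xn == 0:
        raise ValueError("zero-variance input map")
    excl = {e.lower() for e in exclusions}
    keep = [i for i, t in enumerate(terms.terms) if t.lower() not in excl]
    dropped = [t for t in terms.terms if t.lower() in excl]
    if not keep:
        raise ValueError("no terms remain after exclusion")
    M = terms.maps[:, keep]
    Mc = M - M.mean(axis=0, keepdims=True)
    Mn = np.sqrt(np.sum(Mc * Mc, axis=0))
    r = (Mc.T @ xc) / (Mn * xn)
    table = pd.DataFrame({"term": [terms.terms[i] for i in keep], "r": r})
    table = table.sort_values(["r", "term"], ascending=[False, True],
                              kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return DecodingResult(table=table, excluded_terms=dropped)


def load_term_maps(manifest_csv: str | Path, mask: AnalysisMask) -> TermMapSet:
    """Read real term maps from a (term,path) manifest of NIfTI volumes."""
    manifest = pd.read_csv(manifest_csv)
    if not {"term", "path"} <= set(manifest.columns):
        raise ValueError("manifest needs 'term' and 'path' columns")
    base = Path(manifest_csv).parent
    cols = []
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        cols.append(vectorize(load_volume(p, name=str(row["term"])), mask))
    return TermMapSet(terms=[str(t) for t in manifest["term"]],
                      maps=np.column_stack(cols))
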