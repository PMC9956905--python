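"""Hypergeometric pathway over-representation analysis (ORA).

A query set of significant metabolites is tested against every pathway of a
GMT-style library: the p-value is the upper-tail hypergeometric probability
of drawing at least the observed number of pathway members when ``|query|``
metabolites are sampled without replacement from the background.  Holm
step-down adjusted p-values are reported alongside the raw ones.

The bundled library is a hand-curated, synthetic snapshot of ~14 KEGG-style
bovine pathways restricted to the package's 30-metabolite panel; the
background set is the union of all library members and is declared in every
result table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from scipy import stats

__all__ = ["PathwayLibrary", "overrepresent", "load_library", "bundled_library"]


@dataclass
class PathwayLibrary:
    """Pathway name → member set, plus the background universe."""

    pathways: dict[str, frozenset[str]]
    background: frozenset[str]
    descriptions: dict[str, str]

    def __post_init__(self) -> None:
        for name, members in self.pathways.items():
            if not members:
                raise ValueError(f"pathway {name!r} is empty")
            if not members <= self.background:
                raise ValueError(f"pathway {name!r} has members outside the background")

    @property
    def n_background(self) -> int:
        return len(self.background)


def load_library(path: str | Path) -> PathwayLibrary:
    """Read a GMT file: pathway <tab> description <tab> member..."""
    pathways: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    members_all: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, desc, *members = parts
        members = [m.strip() for m in members if m.strip()]
        pathways[name] = frozenset(members)
        descriptions[name] = desc
        members_all.update(members)
    return PathwayLibrary(pathways, frozenset(members_all), descriptions)


def bundled_library() -> PathwayLibrary:
    """The synthetic KEGG-style snapshot shipped with the package."""
    with resources.as_file(resources.files("nmrmeat.data") / "pathways.gmt") as p:
        return load_library(p)


def overrepresent(
    query: set[str] | list[str],
    library: PathwayLibrary | None = None,
) -> pd.DataFrame:
    """ORA of a metabolite set against the library; rows sorted by raw p.

    Query names outside the background are reported in the ``unmapped``
    attribute of the returned frame rather than raising.
    """
    from statsmodels.stats.multitest import multipletests

    library = library if library is not None else bundled_library()
    query = set(query)
    mapped = query & library.background
    unmapped = sorted(query - library.background)
    if not mapped:
        raise ValueError("no query metabolite maps to the library background")

    M = library.n_background
    n = len(mapped)
    rows = []
    for name, members in library.pathways.items():
        K = len(members)
        hits = len(mapped & members)
        # P(X >= hits) for X ~ Hypergeom(M, K, n); sf(hits-1) is exact
        p = float(stats.hypergeom.sf(hits - 1, M, K, n))
        rows.append(
            {
                "pathway": name,
                "hits": hits,
                "pathway_size": K,
                "query_size": n,
                "background_size": M,
                "p_value": min(max(p, 0.0), 1.0),
            }
        )
    df = pd.DataFrame(rows).sort_values("p_value", kind="stable").reset_index(drop=True)
    df["p_holm"] = multipletests(df["p_value"], method="holm")[1]
    df.attrs["unmapped"] = unmapped
    df.attrs["background"] = sorted(library.background)
    return df
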