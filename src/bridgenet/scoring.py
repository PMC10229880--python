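"""Questionnaire scoring: Likert validation, node scores, descriptives, reliability.

Two instruments are supported out of the box: the Spence Children's Anxiety
Scale, short version (SCAS-S; 19 items, five symptom dimensions, 4-point
0-3 coding) and the Internet Gaming Disorder Scale (IGDS; 9 items matching
the DSM-5 IGD criteria, 5-point 1-5 coding).  Network nodes are the five
SCAS-S dimension sums plus the nine raw IGDS items, giving the 14-node
two-community layout used throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScaleDefinition",
    "ItemResponseTable",
    "NodeScoreTable",
    "scas_short",
    "igds",
    "default_scales",
    "load_item_responses",
    "score_scales",
    "descriptive_stats",
    "cronbach_alpha",
]


@dataclass(frozen=True)
class ScaleDefinition:
    """A questionnaire scale: its items, admissible codes and dimensions.

    Parameters
    ----------
    scale_name : str
        Name of the instrument (e.g. ``"SCAS-S"``).
    items : tuple of str
        Ordered item (column) identifiers.
    level_codes : tuple of int
        Admissible response codes, strictly increasing.
    dimensions : dict
        Mapping ``dimension_name -> tuple of items``.  The dimensions must
        partition ``items``.  Singleton dimensions mean the item itself is
        a network node.
    community : str
        Community label assigned to this scale's nodes.
    """

    scale_name: str
    items: tuple
    level_codes: tuple
    dimensions: dict
    community: str

    def __post_init__(self):
        codes = tuple(self.level_codes)
        if len(codes) < 2 or any(b <= a for a, b in zip(codes, codes[1:])):
            raise ValueError("level_codes must be strictly increasing")
        pooled = [it for d in self.dimensions.values() for it in d]
        if sorted(pooled) != sorted(self.items) or len(set(pooled)) != len(pooled):
            raise ValueError(
                f"{self.scale_name}: dimensions must partition the item list"
            )
        for name, its in self.dimensions.items():
            if len(its) == 0:
                raise ValueError(f"{self.scale_name}: dimension {name!r} has no items")


def scas_short(dimensions=None) -> ScaleDefinition:
    """SCAS-S definition: 19 items, codes 0-3, five anxiety dimensions.

    The published instrument does not fix which item belongs to which
    dimension in a machine-readable form, so the partition is configurable;
    the shipped default splits the 19 items into dimensions of sizes
    (4, 4, 3, 4, 4) labelled A1..A5 (separation anxiety, social phobia,
    panic disorder, physical injury fear, generalized anxiety) and is meant
    for synthetic fixtures.  Pass ``dimensions`` to supply the real mapping.
    """
    items = tuple(f"SCAS{i}" for i in range(1, 20))
    if dimensions is None:
        sizes = {"A1": 4, "A2": 4, "A3": 3, "A4": 4, "A5": 4}
        dimensions, k = {}, 0
        for name, sz in sizes.items():
            dimensions[name] = items[k : k + sz]
            k += sz
    return ScaleDefinition(
        scale_name="SCAS-S",
        items=items,
        level_codes=(0, 1, 2, 3),
        dimensions={k: tuple(v) for k, v in dimensions.items()},
        community="anxiety",
    )


def igds() -> ScaleDefinition:
    """IGDS definition: 9 items coded 1-5, one singleton dimension per item."""
    items = tuple(f"IGDS{i}" for i in range(1, 10))
    dims = {f"IGD{i}": (items[i - 1],) for i in range(1, 10)}
    return ScaleDefinition(
        scale_name="IGDS",
        items=items,
        level_codes=(1, 2, 3, 4, 5),
        dimensions=dims,
        community="IGD",
    )


def default_scales() -> list:
    """The two default instruments, SCAS-S then IGDS."""
    return [scas_short(), igds()]


@dataclass
class ItemResponseTable:
    """Validated complete-case item responses.

    ``retention`` is the percentage of submitted rows that survived
    validation (complete, all codes admissible).
    """

    responses: pd.DataFrame
    scale_of_item: dict
    n_submitted: int
    n_valid: int
    n_dropped: int = 0

    @property
    def retention(self) -> float:
        return 100.0 * self.n_valid / self.n_submitted


@dataclass
class NodeScoreTable:
    """Respondent x node scores plus the node -> community partition."""

    scores: pd.DataFrame
    community_of_node: dict = field(default_factory=dict)

    @property
    def node_labels(self):
        return list(self.scores.columns)

    @property
    def n(self) -> int:
        return len(self.scores)

    def communities(self):
        """Distinct community labels in node order."""
        seen = []
        for v in self.community_of_node.values():
            if v not in seen:
                seen.append(v)
        return seen


def load_item_responses(source, defs, id_column=None) -> ItemResponseTable:
    """Read and validate item-level responses.

    Parameters
    ----------
    source : path or DataFrame
        Delimited table with a header row naming the items, or an
        already-loaded DataFrame.
    defs : list of ScaleDefinition
        Must cover every item column in the file.
    id_column : str, optional
        Column holding respondent identifiers; used as the index.

    Rows with any missing or inadmissible cell are dropped (complete-case
    policy) and counted; the retention rate is available on the result.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)
    if id_column is not None:
        df = df.set_index(id_column)

    known = {}
    for d in defs:
        for it in d.items:
            known[it] = d
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise ValueError(f"unknown item column(s): {unknown}")
    missing = [it for it in known if it not in df.columns]
    if missing:
        raise ValueError(f"item column(s) absent from file: {missing}")

    n_submitted = len(df)
    num = df.apply(pd.to_numeric, errors="coerce")
    ok = pd.Series(True, index=df.index)
    for col in num.columns:
        admissible = set(known[col].level_codes)
        ok &= num[col].isin(list(admissible))
    valid = num.loc[ok].astype(int)
    n_valid = len(valid)
    if n_valid == 0:
        raise ValueError("no valid rows after complete-case filtering")
    return ItemResponseTable(
        responses=valid,
        scale_of_item={it: d.scale_name for it, d in known.items()},
        n_submitted=n_submitted,
        n_valid=n_valid,
        n_dropped=n_submitted - n_valid,
    )


def score_scales(responses, defs) -> NodeScoreTable:
    """Produce the node score table: dimension sums for multi-item dimensions,
    raw codes for singleton dimensions.

    Node columns follow the order of ``defs`` and, within a scale, the order
    of its ``dimensions`` mapping (A1..A5 then IGD1..IGD9 for the defaults).
    """
    df = responses.responses if isinstance(responses, ItemResponseTable) else responses
    cols, community = {}, {}
    for d in defs:
        for dim_name, its in d.dimensions.items():
            if len(its) == 0:
                raise ValueError(f"dimension {dim_name!r} has no items")
            cols[dim_name] = df[list(its)].sum(axis=1)
            community[dim_name] = d.community
    scores = pd.DataFrame(cols, index=df.index)
    return NodeScoreTable(scores=scores, community_of_node=community)


def descriptive_stats(scores) -> pd.DataFrame:
    """Per-node mean and sample (n-1 denominator) standard deviation."""
    df = scores.scores if isinstance(scores, NodeScoreTable) else pd.DataFrame(scores)
    if len(df) < 2:
        raise ValueError("need at least 2 respondents for descriptives")
    return pd.DataFrame({"mean": df.mean(axis=0), "sd": df.std(axis=0, ddof=1)})


def cronbach_alpha(items) -> float:
    """Cronbach's alpha, ``k/(k-1) * (1 - sum item variances / total variance)``.

    Variances use the n-1 denominator.  Raises if the total score has zero
    variance (alpha undefined).
    """
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >=2 respondents and >=2 items")
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))
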