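"""Categorization of model MF terminals by their GC-dendrite composition.

GCs are grouped by parallel-fiber depth: D (deep, IDs 1-1000), M (middle,
1001-2000) and S (superficial, 2001-3000) in the default 3000-GC model.
Glomeruli (MF terminals) are then partitioned three ways: uniformly at
random into three populations; by *dominancy* (for each depth group, the
terminals whose dendrite fraction of that group ranks in the top 33%); or by
the full *order* of the three group counts, giving six populations such as
"S>D>M".  Labeled-dendrite counts summarised per population reveal whether
terminal identity predicts which GC cohorts it samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .labeling import LabelingScheme, count_labeled_dendrites
from .network import BipartiteNetwork

GROUPS = ("D", "M", "S")

#: The six order-dependent population labels, e.g. "S>D>M" means S most
#: abundant, M fewest.
ORDER_LABELS = tuple(
    ">".join(p) for p in (
        ("D", "M", "S"), ("D", "S", "M"), ("M", "D", "S"),
        ("M", "S", "D"), ("S", "D", "M"), ("S", "M", "D"),
    )
)


@dataclass(frozen=True)
class GCGroupBounds:
    """Inclusive ID ranges of the D/M/S depth groups; must partition 1..n_gc."""

    d_range: tuple[int, int] = (1, 1000)
    m_range: tuple[int, int] = (1001, 2000)
    s_range: tuple[int, int] = (2001, 3000)

    def group_of(self, gc_ids: np.ndarray) -> np.ndarray:
        """Map GC IDs to group indices 0=D, 1=M, 2=S."""
        out = np.full(gc_ids.shape, -1, dtype=np.int8)
        for gi, (lo, hi) in enumerate((self.d_range, self.m_range, self.s_range)):
            out[(gc_ids >= lo) & (gc_ids <= hi)] = gi
        if (out < 0).any():
            raise ValueError("group bounds do not cover all GC IDs")
        return out


def group_counts(
    network: BipartiteNetwork, bounds: GCGroupBounds | None = None
) -> np.ndarray:
    """(n_glom, 3) matrix of D/M/S dendrite counts per glomerulus."""
    bounds = bounds or GCGroupBounds()
    grp = bounds.group_of(network.gc_ids)
    counts = np.zeros((network.n_glom, 3), dtype=np.int64)
    np.add.at(counts, (network.glom_ids - 1, grp), 1)
    return counts


def categorize_random(
    network: BipartiteNetwork, seed: int | None = None
) -> pd.Series:
    """Uniform random partition of glomeruli into 3 near-equal populations.

    Returns a Series indexed by glom_id with values "pop1"/"pop2"/"pop3".
    """
    rng = np.random.default_rng(seed)
    n = network.n_glom
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=object)
    for k, chunk in enumerate(np.array_split(perm, 3)):
        labels[chunk] = f"pop{k + 1}"
    return pd.Series(labels, index=pd.RangeIndex(1, n + 1, name="glom_id"))


def categorize_dominancy(
    network: BipartiteNetwork,
    bounds: GCGroupBounds | None = None,
    top_fraction: float = 0.33,
) -> Mapping[str, np.ndarray]:
    """Dominant-terminal populations per depth group.

    For each group, glomeruli are ranked by that group's dendrite *fraction*
    (count / degree) in descending order and the top ``top_fraction`` (floor,
    ties at the cutoff included) form that group's dominant population.
    Populations may overlap and need not cover every glomerulus.  Returns a
    mapping group label -> sorted array of 1-based glomerulus ids.
    """
    counts = group_counts(network, bounds)
    deg = counts.sum(axis=1)
    out: dict[str, np.ndarray] = {}
    n_top = int(np.floor(top_fraction * network.n_glom))
    with np.errstate(invalid="ignore", divide="ignore"):
        fracs = np.where(deg[:, None] > 0, counts / np.maximum(deg, 1)[:, None], 0.0)
    for gi, label in enumerate(GROUPS):
        f = fracs[:, gi]
        order = np.argsort(-f, kind="stable")
        if n_top == 0:
            out[label] = np.array([], dtype=np.int64)
            continue
        cutoff = f[order[n_top - 1]]
        chosen = np.flatnonzero(f >= cutoff)  # include cutoff ties
        out[label] = np.sort(chosen + 1)
    return out


def categorize_order(
    network: BipartiteNetwork, bounds: GCGroupBounds | None = None
) -> pd.Series:
    """Order-dependent categorization into six populations.

    D/M/S dendrite counts per glomerulus are ranked from most abundant (0)
    to fewest (2); count ties are broken by the fixed group order D, M, S.
    Returns a Series indexed by glom_id with values like "S>D>M".
    """
    counts = group_counts(network, bounds)
    # lexsort: primary key -count, tie-break by group index (D before M before S)
    n = counts.shape[0]
    labels = np.empty(n, dtype=object)
    group_idx = np.arange(3)
    for i in range(n):
        order = np.lexsort((group_idx, -counts[i]))
        labels[i] = ">".join(GROUPS[g] for g in order)
    return pd.Series(labels, index=pd.RangeIndex(1, n + 1, name="glom_id"))


def population_label_summary(
    network: BipartiteNetwork,
    assignment: pd.Series | Mapping[str, np.ndarray],
    scheme: LabelingScheme,
) -> pd.DataFrame:
    """Mean labeled-dendrite counts per terminal population, one configuration.

    ``assignment`` is either a per-glomerulus Series (random / order
    criteria) or a mapping population -> glomerulus ids (dominancy).
    Returns columns population, mean_n_tdt, mean_n_gfp, n_glomeruli.
    """
    counts = count_labeled_dendrites(network, scheme).set_index("glom_id")
    rows = []
    if isinstance(assignment, pd.Series):
        pops = {p: assignment.index[assignment == p].to_numpy()
                for p in sorted(assignment.unique())}
    else:
        pops = dict(assignment)
    for pop, ids in pops.items():
        sub = counts.loc[np.asarray(ids, dtype=np.int64)]
        rows.append(
            {
                "population": pop,
                "mean_n_tdt": float(sub["n_tdt"].mean()) if len(sub) else 0.0,
                "mean_n_gfp": float(sub["n_gfp"].mean()) if len(sub) else 0.0,
                "n_glomeruli": len(sub),
            }
        )
    return pd.DataFrame(rows)


def averaged_population_summary(
    summaries: list[pd.DataFrame],
) -> pd.DataFrame:
    """Average per-population summaries over configurations.

    Populations are matched by label; ``n_configs`` records how many
    configurations contributed.
    """
    cat = pd.concat(summaries, ignore_index=True)
    out = (
        cat.groupby("population", as_index=False)
        .agg(
            mean_n_tdt=("mean_n_tdt", "mean"),
            mean_n_gfp=("mean_n_gfp", "mean"),
            n_glomeruli=("n_glomeruli", "mean"),
            n_configs=("population", "size"),
        )
    )
    return out
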