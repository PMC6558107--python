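"""Four-group interaction statistics around a focal species set.

All ordered interactions among an analyzed species universe are split by
a focal set F into: "within" (F -> F), "affecting" (F -> others),
"affected" (others -> F) and "background" (others -> others, optionally
minus pairs touching an exclusion set — used when contrasting
disease-enriched bacteria with probiotics already excluded).  Group
proportions of inhibitory/promoting interactions are compared pairwise
by chi-square tests and the signed-weight distributions by two-sided
rank-sum tests, mirroring the published four-group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from ._stats import RankSumResult, rank_sum_test
from .model import ValidationError
from .weights import InteractionMatrix

GROUP_NAMES = ("background", "within", "affecting", "affected")
INHIBITORY = "inhibitory"
PROMOTING = "promoting"


@dataclass(frozen=True)
class FourGroupPartition:
    focal: frozenset
    exclude: frozenset
    #: group name -> list of (source, target, signed_w)
    groups: dict

    @property
    def sizes(self) -> dict:
        return {name: len(self.groups[name]) for name in GROUP_NAMES}

    def weights(self, name: str) -> np.ndarray:
        return np.array([w for _, _, w in self.groups[name]], dtype=float)


def partition_interactions(
    matrix: InteractionMatrix,
    universe,
    focal,
    exclude_from_background=(),
) -> FourGroupPartition:
    """Assign every ordered interaction among ``universe`` to a group.

    ``exclude_from_background`` drops from the background any pair whose
    source or target is in it (it must be disjoint from ``focal``).
    """
    universe = set(universe)
    focal = frozenset(focal)
    exclude = frozenset(exclude_from_background)
    if not focal:
        raise ValidationError("focal set is empty: no contrast possible")
    if not focal <= universe:
        raise ValidationError(
            f"focal species outside universe: {sorted(focal - universe)}"
        )
    if focal & exclude:
        raise ValidationError(
            f"exclusion set overlaps focal set: {sorted(focal & exclude)}"
        )
    groups: dict[str, list] = {name: [] for name in GROUP_NAMES}
    for (target, source), w in matrix.items():
        if source not in universe or target not in universe or source == target:
            continue
        s_f = source in focal
        t_f = target in focal
        if s_f and t_f:
            name = "within"
        elif s_f:
            name = "affecting"
        elif t_f:
            name = "affected"
        else:
            if source in exclude or target in exclude:
                continue
            name = "background"
        groups[name].append((source, target, float(w)))
    return FourGroupPartition(focal=focal, exclude=exclude, groups=groups)


@dataclass(frozen=True)
class GroupSummary:
    name: str
    n: int
    prop_inhibitory: float  # fraction with w < 0
    prop_promoting: float  # fraction with w > 0
    prop_zero: float
    median: float
    q1: float
    q3: float


def summarize_groups(partition: FourGroupPartition) -> list[GroupSummary]:
    out = []
    for name in GROUP_NAMES:
        w = partition.weights(name)
        n = w.size
        if n == 0:
            out.append(GroupSummary(name, 0, *(float("nan"),) * 6))
            continue
        out.append(
            GroupSummary(
                name=name,
                n=int(n),
                prop_inhibitory=float((w < 0).mean()),
                prop_promoting=float((w > 0).mean()),
                prop_zero=float((w == 0).mean()),
                median=float(np.median(w)),
                q1=float(np.percentile(w, 25)),
                q3=float(np.percentile(w, 75)),
            )
        )
    return out


@dataclass(frozen=True)
class PairwiseTest:
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    skipped: bool = False
    note: str = ""


def _chi_square_2x2(k1: int, n1: int, k2: int, n2: int, correction: bool) -> tuple[float, float]:
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table.sum(axis=0) == 0).any():
        # both groups all-effect or all-non-effect: proportions equal
        return 0.0, 1.0
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def proportion_tests(
    partition: FourGroupPartition,
    effect: str = INHIBITORY,
    correction: bool = False,
) -> list[PairwiseTest]:
    """Chi-square contrasts of effect proportions for all 6 group pairs.

    ``effect`` selects inhibitory (w < 0) or promoting (w > 0)
    interactions; each 2x2 table is (effect count, rest) per group.
    Yates correction is off by default.  Empty groups skip their pairs.
    """
    if effect not in (INHIBITORY, PROMOTING):
        raise ValidationError(f"unknown effect {effect!r}")
    out = []
    for a, b in combinations(GROUP_NAMES, 2):
        wa, wb = partition.weights(a), partition.weights(b)
        if wa.size == 0 or wb.size == 0:
            out.append(
                PairwiseTest(a, b, float("nan"), float("nan"), skipped=True,
                             note="empty group")
            )
            continue
        ka = int((wa < 0).sum()) if effect == INHIBITORY else int((wa > 0).sum())
        kb = int((wb < 0).sum()) if effect == INHIBITORY else int((wb > 0).sum())
        statistic, p = _chi_square_2x2(ka, wa.size, kb, wb.size, correction)
        out.append(PairwiseTest(a, b, statistic, p))
    return out


def weight_tests(partition: FourGroupPartition) -> list[PairwiseTest]:
    """Two-sided rank-sum contrasts of signed weights for all 6 group pairs."""
    out = []
    for a, b in combinations(GROUP_NAMES, 2):
        wa, wb = partition.weights(a), partition.weights(b)
        if wa.size == 0 or wb.size == 0:
            out.append(
                PairwiseTest(a, b, float("nan"), float("nan"), skipped=True,
                             note="empty group")
            )
            continue
        res: RankSumResult = rank_sum_test(wa, wb)
        out.append(PairwiseTest(a, b, res.statistic, res.p_value, note=res.method))
    return out


def plot_group_comparison(partition: FourGroupPartition, prefix: str, effect: str = INHIBITORY) -> list[str]:
    """Convenience bar/box plots of the four groups; returns written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summaries = summarize_groups(partition)
    paths = []
    fig, ax = plt.subplots(figsize=(5, 4))
    prop = [
        s.prop_inhibitory if effect == INHIBITORY else s.prop_promoting
        for s in summaries
    ]
    ax.bar(GROUP_NAMES, prop, color="steelblue")
    ax.set_ylabel(f"proportion {effect}")
    fig.tight_layout()
    bar_path = f"{prefix}_proportions.png"
    fig.savefig(bar_path, dpi=120)
    plt.close(fig)
    paths.append(bar_path)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot(
        [partition.weights(name) for name in GROUP_NAMES],
        tick_labels=GROUP_NAMES,
        showfliers=False,
    )
    ax.set_ylabel("signed weight (log2)")
    fig.tight_layout()
    box_path = f"{prefix}_weights.png"
    fig.savefig(box_path, dpi=120)
    plt.close(fig)
    paths.append(box_path)
    return paths
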