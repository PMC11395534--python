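"""Intuitive-rational train/test split.

The dataset comes from several source publications (assay groups).  The
split keeps each group's structural and activity coverage: within a
group, compounds are ordered by increasing activity and test compounds
are picked at evenly spaced ranks, symmetric about the median, with the
least- and most-active compound of every group always kept in training.
Per-group test counts follow largest-remainder proportional allocation
of the overall test fraction.  The procedure is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["GroupedDataset", "intuitive_rational_split"]


@dataclass
class GroupedDataset:
    """Compounds with activities, organised by source group.

    ``groups`` maps a source label to a list of ``(name, pIC50)`` pairs
    (any payload object may stand in for the name as long as it sorts
    deterministically by its string form).
    """

    groups: dict[str, list[tuple[object, float]]] = field(default_factory=dict)

    def add(self, group: str, name: object, pic50: float) -> None:
        self.groups.setdefault(group, []).append((name, pic50))

    @property
    def n_total(self) -> int:
        return sum(len(g) for g in self.groups.values())


def _allocate_counts(sizes: list[int], test_fraction: float) -> list[int]:
    """Largest-remainder allocation of round(fraction * N) test slots."""
    total = int(round(test_fraction * sum(sizes)))
    quotas = [g * test_fraction for g in sizes]
    counts = [int(q) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    # hand out the leftover slots to the largest remainders (ties: group order)
    order = sorted(range(len(sizes)), key=lambda i: (-remainders[i], i))
    for i in order[: max(0, total - sum(counts))]:
        counts[i] += 1
    # extremes rule: a group smaller than 3 cannot give up a compound
    return [0 if g < 3 else min(c, g - 2) for g, c in zip(sizes, counts)]


def _test_ranks(g: int, m: int) -> list[int]:
    """m evenly spaced ranks in 1..g-2, symmetric about the group median."""
    ranks: list[int] = []
    for j in range(1, m + 1):
        r = int(j * (g - 1) / (m + 1) + 0.5)  # round half up, deterministic
        r = min(max(r, 1), g - 2)  # nudge off the extremes
        while r in ranks:  # resolve collisions upward
            r += 1
        ranks.append(r)
    if max(ranks) > g - 2:
        raise ValueError(f"cannot place {m} test compounds in a group of {g}")
    return ranks


def intuitive_rational_split(
    data: GroupedDataset, test_fraction: float = 0.2
) -> tuple[list[tuple[str, object, float]], list[tuple[str, object, float]]]:
    """Split into (train, test) lists of ``(group, name, pIC50)`` tuples.

    Within each group, compounds are sorted by increasing activity
    (ties broken by name) and test members are chosen at symmetric,
    evenly spaced ranks excluding both extremes.  Same input, same
    split.
    """
    if not 0.0 < test_fraction < 0.5:
        raise ValueError("test_fraction must lie in (0, 0.5)")
    labels = list(data.groups)
    if any(len(data.groups[g]) == 0 for g in labels):
        raise ValueError("every group must be nonempty")
    sizes = [len(data.groups[g]) for g in labels]
    counts = _allocate_counts(sizes, test_fraction)

    train, test = [], []
    for label, m in zip(labels, counts):
        members = sorted(data.groups[label], key=lambda nv: (nv[1], str(nv[0])))
        picks = set(_test_ranks(len(members), m)) if m else set()
        for rank, (name, y) in enumerate(members):
            (test if rank in picks else train).append((label, name, y))
    return train, test
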