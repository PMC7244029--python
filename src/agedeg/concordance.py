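"""Concordance between two directional DEG sets.

Cross-tabulates, e.g., the genes up/down-regulated in low physical-ability
worms against those up/down-regulated with chronological age: concordant
cells (up-up, down-down) and discordant cells (up-down, down-up), plus a
percent overlap relative to a configurable denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["DirectionalGeneSet", "ConcordanceTable", "overlap_table", "deg_fraction"]


@dataclass
class DirectionalGeneSet:
    """Named sets of up- and down-regulated gene ids (disjoint)."""

    name: str
    up: set = field(default_factory=set)
    down: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.up = set(self.up)
        self.down = set(self.down)
        both = self.up & self.down
        if both:
            raise ValueError(
                f"{self.name}: genes in both up and down sets: {sorted(both)[:5]}"
            )

    @property
    def n_total(self) -> int:
        return len(self.up) + len(self.down)


@dataclass(frozen=True)
class ConcordanceTable:
    """Direction cross-tabulation of two DEG sets."""

    n_up_up: int
    n_down_down: int
    n_up_down: int  # up in A, down in B
    n_down_up: int
    n_a: int
    n_b: int
    percent_overlap: float
    denominator: str

    @property
    def n_concordant(self) -> int:
        return self.n_up_up + self.n_down_down

    def to_dict(self) -> dict:
        return {
            "n_up_up": self.n_up_up,
            "n_down_down": self.n_down_down,
            "n_up_down": self.n_up_down,
            "n_down_up": self.n_down_up,
            "n_concordant": self.n_concordant,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "percent_overlap": self.percent_overlap,
            "denominator": self.denominator,
        }


def overlap_table(
    set_a: DirectionalGeneSet,
    set_b: DirectionalGeneSet,
    denominator: str = "a",
) -> ConcordanceTable:
    """Exact intersection counts for the four direction pairs.

    ``percent_overlap`` is 100 * concordant / denominator, where the
    denominator is the DEG total of set A (default), of set B, or of the
    union of both DEG universes.
    """
    n_uu = len(set_a.up & set_b.up)
    n_dd = len(set_a.down & set_b.down)
    n_ud = len(set_a.up & set_b.down)
    n_du = len(set_a.down & set_b.up)
    denoms = {
        "a": set_a.n_total,
        "b": set_b.n_total,
        "union": len(set_a.up | set_a.down | set_b.up | set_b.down),
    }
    if denominator not in denoms:
        raise ValueError(f"denominator must be one of {sorted(denoms)}, got {denominator!r}")
    d = denoms[denominator]
    pct = 100.0 * (n_uu + n_dd) / d if d > 0 else 0.0
    return ConcordanceTable(
        n_up_up=n_uu,
        n_down_down=n_dd,
        n_up_down=n_ud,
        n_down_up=n_du,
        n_a=set_a.n_total,
        n_b=set_b.n_total,
        percent_overlap=pct,
        denominator=denominator,
    )


def deg_fraction(n_up: int, n_down: int, n_total: int) -> float:
    """Percent of the probed genes called differentially expressed.

    Returns 100 * (n_up + n_down) / n_total rounded to one decimal — e.g.
    1075 up + 1091 down out of 20,115 genes on the array gives 10.8.
    """
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if n_up < 0 or n_down < 0:
        raise ValueError("counts must be >= 0")
    if n_up + n_down > n_total:
        raise ValueError("n_up + n_down cannot exceed n_total")
    return round(100.0 * (n_up + n_down) / n_total, 1)
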