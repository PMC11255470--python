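"""Red List assessments and per-iteration extinction-probability sampling.

Each scoring iteration draws an extinction probability ``p_i`` for every
taxon from a distribution keyed on its Red List category. Extinct (EX) and
Extinct-in-the-Wild (EW) taxa get ``p_i = 1`` exactly; Data Deficient and
Not Evaluated taxa are sampled from the full (pooled) distribution, which
propagates assessment uncertainty into the scores.

The published EDGE2 protocol defers the exact category->probability
distribution to its own supplement, so the sampler here is deliberately
configurable: the default maps the five data-sufficient categories
(LC < NT < VU < EN < CR) onto the five equal-probability bands of a
right-skewed Beta base distribution, which preserves the protocol's
qualitative contract (stochastic ordering by threat, DD/NE pooled over
all bands) while remaining swappable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CATEGORIES",
    "THREATENED",
    "AssessmentTable",
    "PextSamplerConfig",
    "PextIteration",
    "sample_pext",
]

#: closed Red List vocabulary
CATEGORIES = ("LC", "NT", "VU", "EN", "CR", "EW", "EX", "DD", "NE")
#: ordered data-sufficient, extant categories (least to most threatened)
BANDED = ("LC", "NT", "VU", "EN", "CR")
#: categories admissible to the EDGE Species list
THREATENED = frozenset({"VU", "EN", "CR", "EW", "EX"})
DATA_DEFICIENT = frozenset({"DD", "NE"})


class AssessmentTable:
    """Taxon -> Red List category mapping with a closed vocabulary."""

    def __init__(self, categories: Mapping[str, str]):
        bad = sorted({c for c in categories.values() if c not in CATEGORIES})
        if bad:
            raise ValueError(
                f"unknown Red List categories {bad}; expected one of {CATEGORIES}"
            )
        self.categories: dict[str, str] = dict(categories)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AssessmentTable":
        if not {"taxon", "category"} <= set(df.columns):
            raise ValueError("assessment table needs columns: taxon, category")
        if df["taxon"].duplicated().any():
            dupes = sorted(df.loc[df["taxon"].duplicated(), "taxon"].unique())
            raise ValueError(f"duplicate taxa in assessments: {dupes[:10]}")
        return cls(dict(zip(df["taxon"].astype(str), df["category"].astype(str))))

    @classmethod
    def from_csv(cls, path) -> "AssessmentTable":
        return cls.from_dataframe(pd.read_csv(path))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"taxon": list(self.categories), "category": list(self.categories.values())}
        )

    @property
    def taxa(self) -> list[str]:
        return list(self.categories)

    def __len__(self) -> int:
        return len(self.categories)

    def __getitem__(self, taxon: str) -> str:
        return self.categories[taxon]

    def category_counts(self) -> dict[str, int]:
        """Exact count per category, all vocabulary entries present."""
        counts = dict.fromkeys(CATEGORIES, 0)
        for cat in self.categories.values():
            counts[cat] += 1
        return counts


@dataclass(frozen=True)
class PextSamplerConfig:
    """Configuration of the category -> extinction-probability sampler.

    mode="banded": draw a quantile in the category's band of the Beta base
    distribution (five equal-probability bands ordered LC<NT<VU<EN<CR) and
    invert; DD/NE draw a quantile on the full [0, 1].
    mode="fixed": deterministic per-category values (for exact tests).
    """

    mode: str = "banded"
    beta_a: float = 0.6
    beta_b: float = 2.4
    fixed_values: Mapping[str, float] = field(
        default_factory=lambda: {
            "LC": 0.0625, "NT": 0.125, "VU": 0.25, "EN": 0.5, "CR": 0.9,
        }
    )
    extinct_categories: frozenset = frozenset({"EX", "EW"})

    def __post_init__(self):
        if self.mode not in ("banded", "fixed"):
            raise ValueError(f"unknown sampler mode: {self.mode!r}")
        if self.mode == "fixed":
            vals = [self.fixed_values[c] for c in BANDED]
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise ValueError(
                    "fixed values must be nondecreasing LC -> CR"
                )

    def band(self, category: str) -> tuple[float, float]:
        """Quantile band [lo, hi) of the base distribution for a category."""
        i = BANDED.index(category)
        k = len(BANDED)
        return i / k, (i + 1) / k

    def band_median(self, category: str) -> float:
        lo, hi = self.band(category)
        return float(stats.beta.ppf((lo + hi) / 2.0, self.beta_a, self.beta_b))


@dataclass(frozen=True)
class PextIteration:
    """Per-iteration map taxon -> extinction probability in [0, 1]."""

    iteration: int
    p: Mapping[str, float]

    def __getitem__(self, taxon: str) -> float:
        return self.p[taxon]

    def __len__(self) -> int:
        return len(self.p)


def sample_pext(
    assessments: AssessmentTable,
    config: PextSamplerConfig | None = None,
    iteration: int = 0,
    seed: int | None = None,
) -> PextIteration:
    """Draw one extinction probability per taxon for a scoring iteration.

    Deterministic given ``(seed, iteration, config)``; a seed is required
    (the pipeline's reproducibility contract).
    """
    if config is None:
        config = PextSamplerConfig()
    if seed is None:
        raise ValueError("sample_pext requires a seed for reproducibility")
    rng = np.random.default_rng([int(seed), int(iteration)])
    p: dict[str, float] = {}
    for taxon, cat in assessments.categories.items():
        if cat in config.extinct_categories:
            p[taxon] = 1.0
        elif config.mode == "fixed":
            if cat in DATA_DEFICIENT:
                # fixed mode is deterministic everywhere: DD/NE get the
                # midpoint of the fixed values (the pooled "centre")
                vals = [config.fixed_values[c] for c in BANDED]
                p[taxon] = float(np.median(vals))
            else:
                p[taxon] = float(config.fixed_values[cat])
        else:
            if cat in DATA_DEFICIENT:
                q = rng.uniform(0.0, 1.0)
            else:
                lo, hi = config.band(cat)
                q = rng.uniform(lo, hi)
            p[taxon] = float(stats.beta.ppf(q, config.beta_a, config.beta_b))
    return PextIteration(iteration=iteration, p=p)
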