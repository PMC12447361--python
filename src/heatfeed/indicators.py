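"""WHO infant and young child feeding indicators from 24-h dietary recall.

Classifies each child's previous-day recall into the three binary indicators:

* MDD (minimum dietary diversity): consumed at least 5 of the 8 WHO food
  groups (breastmilk; grains/starchy roots/tubers/plantains; legumes and
  nuts; dairy; flesh foods; eggs; vitamin-A-rich fruits and vegetables;
  other fruits and vegetables).
* MMF (minimum meal frequency): age- and breastfeeding-specific feed counts
  (breastfed 6-8 months: >=2 solid/semi-solid/soft feeds; breastfed 9-23
  months: >=3; non-breastfed 6-23 months: >=4 feeds counting milk feeds,
  with at least one solid/semi-solid/soft feed).
* MAD (minimum acceptable diet): breastfed children must meet both MDD and
  MMF; non-breastfed children must meet a modified diversity rule (>=4 of
  the 6 non-breastmilk, non-dairy groups), MMF, and have at least 2 milk
  feeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column names of the 8 WHO food groups, in the order listed by the standard.
FOOD_GROUP_COLUMNS = [
    "fg_breastmilk",
    "fg_grains",
    "fg_legumes_nuts",
    "fg_dairy",
    "fg_flesh",
    "fg_eggs",
    "fg_vita_fruit_veg",
    "fg_other_fruit_veg",
]

#: The six groups entering the non-breastfed MAD diversity rule
#: (the eight groups minus breastmilk and minus dairy).
NON_BF_MAD_GROUPS = [
    c for c in FOOD_GROUP_COLUMNS if c not in ("fg_breastmilk", "fg_dairy")
]

MIN_AGE_MONTHS, MAX_AGE_MONTHS = 6, 23


@dataclass(frozen=True)
class DietRecall:
    """One child's 24-h dietary recall."""

    food_groups: tuple  # 8 booleans, FOOD_GROUP_COLUMNS order
    meal_count: int  # solid/semi-solid/soft feeds
    milk_feed_count: int
    is_breastfed: bool

    def __post_init__(self) -> None:
        if len(self.food_groups) != 8:
            raise ValueError("food_groups must have exactly 8 entries")
        if self.meal_count < 0 or self.milk_feed_count < 0:
            raise ValueError("feed counts must be non-negative")
        if self.is_breastfed and not self.food_groups[0]:
            raise ValueError("breastfed child must have the breastmilk group set")


@dataclass(frozen=True)
class IndicatorSet:
    mdd: bool
    mmf: bool
    mad: bool


def _check_age(age_months) -> None:
    a = np.asarray(age_months)
    if np.any(a < MIN_AGE_MONTHS) or np.any(a > MAX_AGE_MONTHS):
        raise ValueError(f"age_months outside [{MIN_AGE_MONTHS}, {MAX_AGE_MONTHS}]")


def classify_mdd(recall: DietRecall) -> bool:
    """Minimum dietary diversity: at least 5 of the 8 food groups."""
    return int(sum(bool(g) for g in recall.food_groups)) >= 5


def classify_mmf(recall: DietRecall, age_months: int) -> bool:
    """Minimum meal frequency, by age and breastfeeding status."""
    _check_age(age_months)
    if recall.is_breastfed:
        need = 2 if age_months <= 8 else 3
        return recall.meal_count >= need
    return (recall.meal_count + recall.milk_feed_count >= 4) and recall.meal_count >= 1


def classify_mad(recall: DietRecall, age_months: int) -> bool:
    """Minimum acceptable diet (composite of diversity and frequency)."""
    _check_age(age_months)
    mmf = classify_mmf(recall, age_months)
    if recall.is_breastfed:
        return classify_mdd(recall) and mmf
    groups = dict(zip(FOOD_GROUP_COLUMNS, recall.food_groups))
    diversity6 = sum(bool(groups[c]) for c in NON_BF_MAD_GROUPS) >= 4
    return diversity6 and mmf and recall.milk_feed_count >= 2


def classify(recall: DietRecall, age_months: int) -> IndicatorSet:
    return IndicatorSet(
        mdd=classify_mdd(recall),
        mmf=classify_mmf(recall, age_months),
        mad=classify_mad(recall, age_months),
    )


def classify_frame(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorised indicator classification over a records frame.

    Needs the FOOD_GROUP_COLUMNS plus meal_count, milk_feed_count,
    is_breastfed, age_months.  Returns a frame with boolean columns
    mdd/mmf/mad indexed like ``records`` (by record_id when present).
    """
    age = records["age_months"].to_numpy()
    _check_age(age)
    fg = records[FOOD_GROUP_COLUMNS].to_numpy(dtype=bool)
    bf = records["is_breastfed"].to_numpy(dtype=bool)
    if np.any(bf & ~fg[:, 0]):
        raise ValueError("breastfed records must have fg_breastmilk set")
    meals = records["meal_count"].to_numpy()
    milk = records["milk_feed_count"].to_numpy()
    if np.any(meals < 0) or np.any(milk < 0):
        raise ValueError("feed counts must be non-negative")

    mdd = fg.sum(axis=1) >= 5
    need = np.where(age <= 8, 2, 3)
    mmf = np.where(bf, meals >= need, (meals + milk >= 4) & (meals >= 1))
    div6 = records[NON_BF_MAD_GROUPS].to_numpy(dtype=bool).sum(axis=1) >= 4
    mad = np.where(bf, mdd & mmf, div6 & mmf & (milk >= 2))

    idx = (
        pd.Index(records["record_id"], name="record_id")
        if "record_id" in records
        else records.index
    )
    return pd.DataFrame({"mdd": mdd, "mmf": mmf, "mad": mad}, index=idx)


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------

def percentage(count: int, total: int) -> float:
    """Percentage at one decimal with half-up rounding; NaN for empty total."""
    if total == 0:
        return float("nan")
    q = Decimal(100 * count) / Decimal(total)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


_AGE_BANDS = [(6, 11, "6-11"), (12, 17, "12-18"), (18, 23, "18-23")]
_MATERNAL_AGE_BANDS = [(36, 200, ">35"), (20, 35, "20-35"), (0, 19, "<20")]


def descriptive_table(records: pd.DataFrame, indicators: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of children NOT meeting each indicator, by stratum.

    Strata: overall, region (when a ``region`` column exists), age band
    (6-11, 12-17 printed as "12-18", 18-23), sex, residence, maternal age
    band.  Percentages are half-up rounded to one decimal; empty strata get
    count 0 and a missing percentage.
    """
    ind = indicators.reindex(
        records["record_id"] if "record_id" in records else records.index
    )
    rows = []

    def add(stratum: str, level: str, mask: np.ndarray) -> None:
        n = int(mask.sum())
        row = {"stratum": stratum, "level": level, "n": n}
        for name in ("mdd", "mmf", "mad"):
            not_met = int((~ind[name].to_numpy())[mask].sum()) if n else 0
            row[f"n_not_{name}"] = not_met
            row[f"pct_not_{name}"] = percentage(not_met, n)
        rows.append(row)

    all_mask = np.ones(len(records), dtype=bool)
    add("total", "all", all_mask)
    if "region" in records:
        for level in pd.unique(records["region"]):
            add("region", str(level), (records["region"] == level).to_numpy())
    age = records["age_months"].to_numpy()
    for lo, hi, label in _AGE_BANDS:
        add("age_months", label, (age >= lo) & (age <= hi))
    if "sex" in records:
        for level in pd.unique(records["sex"]):
            add("sex", str(level), (records["sex"] == level).to_numpy())
    if "urban" in records:
        urb = records["urban"].to_numpy(dtype=bool)
        add("residence", "urban", urb)
        add("residence", "rural", ~urb)
    if "maternal_age" in records:
        mat = records["maternal_age"].to_numpy()
        for lo, hi, label in _MATERNAL_AGE_BANDS:
            add("maternal_age", label, (mat >= lo) & (mat <= hi))
    return pd.DataFrame(rows)


def spearman_screen(records: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Spearman rank correlations over individual/household variables.

    Ties get average ranks; categorical columns are factorised to integer
    codes first.  Constant variables yield missing correlations with a
    warning.  Returns a symmetric matrix with unit diagonal.
    """
    if columns is None:
        columns = [
            c
            for c in (
                "age_months", "sex", "laz", "maternal_age", "education",
                "living_with_partner", "wealth_quintile", "urban",
                "housing_usual", "n_under5", "refrigerator", "air_conditioning",
            )
            if c in records
        ]
    if len(records) < 2:
        raise ValueError("spearman_screen needs at least 2 records")
    mat = np.empty((len(records), len(columns)))
    for j, c in enumerate(columns):
        col = records[c]
        if not np.issubdtype(col.dtype, np.number) and col.dtype != bool:
            col = pd.Series(pd.factorize(col, sort=True)[0], index=col.index)
        mat[:, j] = col.to_numpy(dtype=float)
    constant = np.array([np.all(mat[:, j] == mat[0, j]) for j in range(len(columns))])
    if constant.any():
        logger.warning(
            "spearman_screen: constant variable(s) %s yield undefined correlations",
            [c for c, k in zip(columns, constant) if k],
        )
    rho = pd.DataFrame(mat, columns=columns).corr(method="spearman").to_numpy()
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=columns, columns=columns)
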