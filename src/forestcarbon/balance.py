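"""Decadal carbon-balance bookkeeping: stock change, removals, and the NEP proxy.

Net ecosystem productivity (NEP = NPP minus heterotrophic respiration) is
proxied as the observed biomass stock change plus all quantified removals:

    NEP = dC/dt + R_fire + R_harvest + R_grazing        [tC/ha/yr]

over closed decadal-style intervals between inventory points.  Positive
stock change means net growth exceeded removals and mortality; negative
stock change is permitted and signals losses from factors outside the three
quantified removal terms (insects, windthrow, drought), which appear
implicitly as reduced dC/dt.

Harvest enters as stem removals expanded by biomass expansion factors for
bark, crown (twigs/leaves) and belowground biomass, separately for fuelwood
and industrial wood.  All fluxes and stocks are expressed per unit total
forest area (tC/ha) for comparability across scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import AnnualSeries, Geography, StockPoint, ValidationError, fsum_series

__all__ = [
    "BalanceInterval",
    "ExpansionFactors",
    "ProductRatios",
    "RemovalSeries",
    "compute_balances",
    "cumulative_offsets",
    "expand_harvest",
    "interval_balance",
    "per_area_flux",
    "period_average_balance",
]

REMOVAL_COMPONENTS = ("fire", "harvest", "grazing")


@dataclass(frozen=True)
class ProductRatios:
    """Expansion ratios for one product class, relative to harvested stem mass."""

    bark: float
    crown: float
    root_shoot: float

    def __post_init__(self):
        for name in ("bark", "crown", "root_shoot"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} ratio must be non-negative")

    @property
    def multiplier(self) -> float:
        """Total-biomass multiplier: (1 + bark + crown) * (1 + root:shoot)."""
        return (1.0 + self.bark + self.crown) * (1.0 + self.root_shoot)


@dataclass(frozen=True)
class ExpansionFactors:
    """Per product class (fuelwood, industrial wood) expansion ratios."""

    fuelwood: ProductRatios
    industrial: ProductRatios


@dataclass
class RemovalSeries:
    """Annual removal flux for one component, in tC/yr (plus per-area form)."""

    geography: Geography
    component: str
    series: AnnualSeries
    per_area: AnnualSeries | None = None

    def __post_init__(self):
        if self.component not in REMOVAL_COMPONENTS:
            raise ValidationError(f"unknown removal component {self.component!r}")
        if any(v < 0 for v in self.series.values.values()):
            raise ValidationError("removal fluxes must be non-negative")


@dataclass
class BalanceInterval:
    """One closed interval's carbon balance in tC/ha/yr.

    The identity nep = stock_change_rate + fire + harvest + grazing holds to
    1e-9 by construction; it is validated here, never forced.
    """

    geography: Geography
    t0: int
    t1: int
    stock_change_rate: float
    fire: float
    harvest: float
    grazing: float
    nep: float
    denominator_area: float

    def __post_init__(self):
        if self.t1 <= self.t0:
            raise ValidationError(f"interval must have t1 > t0, got [{self.t0}, {self.t1}]")
        residual = self.nep - (self.stock_change_rate + self.fire + self.harvest + self.grazing)
        if abs(residual) >= 1e-9:
            raise ValidationError(
                f"balance identity violated by {residual:.3e} tC/ha/yr on [{self.t0}, {self.t1}]"
            )

    @property
    def duration(self) -> int:
        return self.t1 - self.t0

    @property
    def removals(self) -> dict[str, float]:
        return {"fire": self.fire, "harvest": self.harvest, "grazing": self.grazing}


def expand_harvest(
    stem: AnnualSeries,
    factors: ExpansionFactors,
    fuelwood_share: AnnualSeries | float,
    geography: Geography,
) -> RemovalSeries:
    """Expand harvested stem mass to total biomass killed.

    Each year's stem removal (tC/yr) is split by the fuelwood share into the
    two product classes and multiplied by the class multiplier
    (1 + bark + crown) * (1 + root:shoot).
    """

    def share_at(y: int) -> float:
        s = fuelwood_share if isinstance(fuelwood_share, float) else fuelwood_share.get(y)
        if s is None:
            raise ValidationError(f"fuelwood share undefined for year {y}")
        if not 0.0 <= s <= 1.0:
            raise ValidationError(f"fuelwood share must be in [0, 1], got {s} in {y}")
        return s

    mf = factors.fuelwood.multiplier
    mi = factors.industrial.multiplier
    values = {}
    for y, v in stem.items():
        s = share_at(y)
        values[y] = v * (s * mf + (1.0 - s) * mi)
    return RemovalSeries(
        geography=geography,
        component="harvest",
        series=AnnualSeries("tC/yr", values, stem.gaps),
    )


def per_area_flux(total: AnnualSeries, denominator: float) -> AnnualSeries:
    """Express a total flux (tC/yr) per unit forest area (tC/ha/yr)."""
    if denominator <= 0:
        raise ValidationError(f"denominator area must be positive, got {denominator}")
    return total.map_values(lambda v: v / denominator, unit="tC/ha/yr")


def _denominator(s0: StockPoint, s1: StockPoint, mode: str) -> float:
    if mode == "start":
        return s0.forest_area
    if mode == "end":
        return s1.forest_area
    if mode == "mean":
        return 0.5 * (s0.forest_area + s1.forest_area)
    raise ValidationError(f"unknown denominator mode {mode!r}")


def interval_balance(
    stock0: StockPoint,
    stock1: StockPoint,
    removals: dict[str, RemovalSeries],
    denominator_mode: str = "mean",
) -> BalanceInterval:
    """Assemble one interval's balance from endpoint stocks and removal series.

    The stock-change rate is the density difference divided by the interval
    length.  Each removal term is the unweighted mean annual per-area flux
    over the half-open year range (t0, t1], with gap years excluded from the
    mean.  NEP is their sum; negative stock change is permitted.
    """
    if stock0.geography != stock1.geography:
        raise ValidationError("stock points must share a geography")
    t0, t1 = stock0.time, stock1.time
    if t1 <= t0:
        raise ValidationError(f"need t1 > t0, got {t0}, {t1}")
    denom = _denominator(stock0, stock1, denominator_mode)
    if denom <= 0:
        raise ValidationError("denominator forest area must be positive")
    dC = (stock1.stock_density - stock0.stock_density) / (t1 - t0)
    terms: dict[str, float] = {}
    for comp in REMOVAL_COMPONENTS:
        if comp not in removals:
            raise ValidationError(f"missing removal component {comp!r}")
        series = removals[comp].series
        vals = [series.get(y) / denom for y in range(t0 + 1, t1 + 1) if y in series]
        if not vals:
            raise ValidationError(
                f"removal series {comp!r} has no defined years in ({t0}, {t1}]"
            )
        terms[comp] = fsum_series(vals) / len(vals)
    nep = dC + terms["fire"] + terms["harvest"] + terms["grazing"]
    return BalanceInterval(
        geography=stock0.geography,
        t0=t0,
        t1=t1,
        stock_change_rate=dC,
        fire=terms["fire"],
        harvest=terms["harvest"],
        grazing=terms["grazing"],
        nep=nep,
        denominator_area=denom,
    )


def compute_balances(
    stocks: list[StockPoint],
    removals: dict[str, RemovalSeries],
    intervals: list[tuple[int, int]],
    denominator_mode: str = "mean",
) -> list[BalanceInterval]:
    """Balance every configured interval from the available stock points."""
    by_time = {s.time: s for s in stocks}
    out = []
    for t0, t1 in intervals:
        if t0 not in by_time or t1 not in by_time:
            raise ValidationError(f"missing stock point at {t0} or {t1}")
        out.append(interval_balance(by_time[t0], by_time[t1], removals, denominator_mode))
    return out


def period_average_balance(intervals: list[BalanceInterval]) -> BalanceInterval:
    """Duration-weighted mean balance over a list of intervals.

    The balance identity is preserved exactly because the weighted mean is
    linear in every component.
    """
    if not intervals:
        raise ValidationError("need at least one interval")
    geos = {iv.geography for iv in intervals}
    if len(geos) != 1:
        raise ValidationError(f"mixed geographies: {sorted(g.code for g in geos)}")
    total = sum(iv.duration for iv in intervals)

    def wmean(attr: str) -> float:
        return fsum_series(getattr(iv, attr) * iv.duration for iv in intervals) / total

    dC = wmean("stock_change_rate")
    fire = wmean("fire")
    harvest = wmean("harvest")
    grazing = wmean("grazing")
    return BalanceInterval(
        geography=intervals[0].geography,
        t0=min(iv.t0 for iv in intervals),
        t1=max(iv.t1 for iv in intervals),
        stock_change_rate=dC,
        fire=fire,
        harvest=harvest,
        grazing=grazing,
        nep=dC + fire + harvest + grazing,
        denominator_area=wmean("denominator_area"),
    )


def cumulative_offsets(intervals: list[BalanceInterval]) -> dict[str, float]:
    """Share (%) of cumulative NEP offset by each removal, plus stock change.

    share_k = sum(flux_k * duration) / sum(nep * duration) * 100.  The three
    removal shares and the stock-change share sum to 100% by the balance
    identity.
    """
    if not intervals:
        raise ValidationError("need at least one interval")
    cum_nep = fsum_series(iv.nep * iv.duration for iv in intervals)
    if cum_nep <= 0:
        raise ValidationError(f"cumulative NEP must be positive, got {cum_nep}")
    shares = {}
    for comp in REMOVAL_COMPONENTS:
        shares[comp] = 100.0 * fsum_series(
            getattr(iv, comp) * iv.duration for iv in intervals
        ) / cum_nep
    shares["stock_change"] = 100.0 * fsum_series(
        iv.stock_change_rate * iv.duration for iv in intervals
    ) / cum_nep
    return shares
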