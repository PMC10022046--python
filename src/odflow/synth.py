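"""Seeded synthetic hospitalization records with gravity-model structure.

The generator makes the whole pipeline testable without any external
download.  Municipalities get uniform-random seats inside a bounding box;
the number of journeys from origin O to provider D in a year is Poisson
with mean

    lambda_OD = theta * pop_O * cap_D * exp(-d_OD / decay_km)

a gravity model with exponential distance decay, which concentrates flow
onto well-capacitated providers the way real referral networks do.

Determinism: every draw comes from a stream keyed by (seed, year, O, D)
(or (seed, kind, index) for registry attributes), so enlarging a scenario
never perturbs the draws of existing municipality pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .geo import GeoPoint, haversine_km
from .records_io import HospitalizationRecord, Municipality

__all__ = ["SyntheticScenario", "generate_registry", "generate_records", "expected_flows"]

# sub-stream tags for the keyed generators
_TAG_COORDS = 0
_TAG_POP = 1
_TAG_CAP = 2

_QUADRANT_LABELS = {
    (False, False): "Southwest",
    (False, True): "Southeast",
    (True, False): "Northwest",
    (True, True): "Northeast",
}


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic record-generation run.

    ``provider_codes`` selects which municipalities offer the procedure;
    codes follow the deterministic scheme ``290001, 290002, ...`` produced
    by :func:`generate_registry`.  ``populations`` and ``capacities`` may
    be given explicitly (code -> positive value) or left ``None`` to be
    drawn log-normally from the seed.
    """

    n_municipalities: int
    provider_codes: Tuple[str, ...]
    years: Tuple[int, ...]
    seed: int = 0
    bounding_box: Tuple[float, float, float, float] = (-18.0, -9.0, -46.0, -38.0)
    theta: float = 1.0
    decay_km: float = 150.0
    procedure_codes: Tuple[str, ...] = ("0406010013",)
    procedure_weights: Optional[Tuple[float, ...]] = None
    populations: Optional[Mapping[str, float]] = None
    capacities: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "provider_codes", tuple(self.provider_codes))
        object.__setattr__(self, "years", tuple(self.years))
        object.__setattr__(self, "procedure_codes", tuple(self.procedure_codes))
        if self.n_municipalities < 1:
            raise ValueError("need at least one municipality")
        if not self.provider_codes:
            raise ValueError("provider_codes must be non-empty")
        codes = set(self.all_codes())
        if not set(self.provider_codes) <= codes:
            raise ValueError("provider_codes must be a subset of the municipality codes")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.decay_km <= 0:
            raise ValueError("decay_km must be > 0")
        lat_min, lat_max, lon_min, lon_max = self.bounding_box
        if lat_min >= lat_max or lon_min >= lon_max:
            raise ValueError("bounding box is degenerate (zero area)")
        if not self.years:
            raise ValueError("years must be non-empty")
        if not self.procedure_codes:
            raise ValueError("procedure_codes must be non-empty")
        if self.procedure_weights is not None:
            w = tuple(float(x) for x in self.procedure_weights)
            if len(w) != len(self.procedure_codes) or any(x < 0 for x in w) or sum(w) == 0:
                raise ValueError("procedure_weights must match procedure_codes and sum > 0")
            object.__setattr__(self, "procedure_weights", w)

    @staticmethod
    def code_for(index: int) -> str:
        """Deterministic 6-digit municipality code of the index-th municipality."""
        return str(290001 + index)

    def all_codes(self) -> List[str]:
        return [self.code_for(i) for i in range(self.n_municipalities)]

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticScenario":
        d = dict(d)
        for key in ("provider_codes", "years", "procedure_codes", "procedure_weights"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "bounding_box" in d and d["bounding_box"] is not None:
            d["bounding_box"] = tuple(d["bounding_box"])
        return cls(**d)


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(list(key))


def _mass(scenario: SyntheticScenario, code: str, explicit: Optional[Mapping[str, float]],
          tag: int) -> float:
    if explicit is not None:
        value = float(explicit[code])
        if value <= 0:
            raise ValueError(f"mass for {code} must be positive")
        return value
    return float(_rng(scenario.seed, tag, int(code)).lognormal(mean=0.0, sigma=0.75))


def population_of(scenario: SyntheticScenario, code: str) -> float:
    """Origin mass of a municipality (explicit or seeded log-normal draw)."""
    return _mass(scenario, code, scenario.populations, _TAG_POP)


def capacity_of(scenario: SyntheticScenario, code: str) -> float:
    """Provider capacity of a municipality (explicit or seeded log-normal draw)."""
    return _mass(scenario, code, scenario.capacities, _TAG_CAP)


def generate_registry(scenario: SyntheticScenario) -> Dict[str, Municipality]:
    """Municipality registry with uniform-random seats inside the box.

    Macroregion labels are assigned by spatial quadrant relative to the
    box centre.  Deterministic given the scenario seed; each
    municipality's coordinates depend only on (seed, index), so growing
    the scenario leaves existing municipalities in place.
    """
    lat_min, lat_max, lon_min, lon_max = scenario.bounding_box
    lat_mid = (lat_min + lat_max) / 2.0
    lon_mid = (lon_min + lon_max) / 2.0
    registry: Dict[str, Municipality] = {}
    for i in range(scenario.n_municipalities):
        code = scenario.code_for(i)
        rng = _rng(scenario.seed, _TAG_COORDS, i)
        lat = float(rng.uniform(lat_min, lat_max))
        lon = float(rng.uniform(lon_min, lon_max))
        registry[code] = Municipality(
            code=code,
            name=f"Synth-{code}",
            lat=lat,
            lon=lon,
            macroregion=_QUADRANT_LABELS[(lat >= lat_mid, lon >= lon_mid)],
        )
    return registry


def expected_flows(
    scenario: SyntheticScenario, registry: Mapping[str, Municipality]
) -> Dict[Tuple[str, str], float]:
    """Per-(origin, provider) Poisson means lambda_OD for one year.

    The analytic counterpart of :func:`generate_records`; useful to check
    monotonicity and convergence properties without sampling.
    """
    lambdas: Dict[Tuple[str, str], float] = {}
    for o in scenario.all_codes():
        for d in scenario.provider_codes:
            if o == d:
                continue
            dist = haversine_km(
                GeoPoint(registry[o].lat, registry[o].lon),
                GeoPoint(registry[d].lat, registry[d].lon),
            )
            lambdas[(o, d)] = (
                scenario.theta
                * population_of(scenario, o)
                * capacity_of(scenario, d)
                * float(np.exp(-dist / scenario.decay_km))
            )
    return lambdas


def generate_records(
    scenario: SyntheticScenario, registry: Mapping[str, Municipality]
) -> List[HospitalizationRecord]:
    """Draw individual journey records for every year of the scenario.

    For each (year, origin, provider) with origin != provider the journey
    count is Poisson(lambda_OD); each journey gets a uniform month in
    1..12 and a procedure code sampled by weight, all from the stream
    keyed by (seed, year, origin, provider).
    """
    lambdas = expected_flows(scenario, registry)
    weights = scenario.procedure_weights
    if weights is not None:
        p = np.asarray(weights, dtype=float)
        p = p / p.sum()
    else:
        p = None
    codes = np.asarray(scenario.procedure_codes)

    records: List[HospitalizationRecord] = []
    for year in sorted(scenario.years):
        for o in scenario.all_codes():
            for d in scenario.provider_codes:
                if o == d:
                    continue
                lam = lambdas[(o, d)]
                rng = _rng(scenario.seed, year, int(o), int(d))
                n = int(rng.poisson(lam))
                if n == 0:
                    continue
                months = rng.integers(1, 13, size=n)
                procs = rng.choice(codes, size=n, p=p)
                for month, proc in zip(months, procs):
                    records.append(
                        HospitalizationRecord(
                            year=year,
                            month=int(month),
                            origin_code=o,
                            dest_code=d,
                            procedure_code=str(proc),
                        )
                    )
    return records
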