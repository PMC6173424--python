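"""Synthetic facility-survey generator with known latent structure.

Real facility-readiness surveys (such as the DHS Service Provision
Assessment) are registration-restricted, so the pipeline is exercised on
simulated matrices that emulate their key features: facilities nested in
country strata with hospitals over-represented at the top of the readiness
distribution, binary items of very unequal informativeness spread over six
domains, blocks of structural zeros where a service is not offered and its
items could not be assessed, and positive sampling weights varying by
stratum.

Item responses follow a two-parameter logistic latent-trait model: facility i
has latent readiness theta_i = country offset + hospital bonus + N(0, 1)
noise, and item j is present with probability
``expit(a_j * (theta_i - b_j))``. Discrimination a_j >= 0 sets how strongly
the item tracks readiness (a_j = 0 gives pure noise); difficulty b_j sets the
readiness level at which presence reaches 50%. Items in a service block are
forced to 0 whenever the facility does not offer the service, regardless of
theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import expit

from .core import DomainMap, ItemMatrix

__all__ = [
    "CountrySpec",
    "ServiceBlock",
    "GeneratorConfig",
    "SyntheticTruth",
    "generate",
    "benchmark_config",
    "benchmark_fixture",
    "sri_like_items",
]


@dataclass(frozen=True)
class CountrySpec:
    name: str
    mean_offset: float       # added to latent readiness for the stratum
    weight_scale: float      # multiplies the facility sampling weights
    share: float             # fraction of facilities in this stratum


@dataclass(frozen=True)
class ServiceBlock:
    """Items observable only where a service is offered."""

    name: str
    item_ids: tuple
    offer_prob: float

    def __post_init__(self):
        if not 0.0 <= self.offer_prob <= 1.0:
            raise ValueError("offer_prob must be in [0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    n_facilities: int
    countries: tuple                      # CountrySpec, shares sum to 1
    hospital_fraction: float
    hospital_bonus: float
    domains: tuple                        # ((name, n_items), ...)
    discrimination: tuple                 # a_j >= 0 per item
    difficulty: tuple                     # b_j per item
    service_blocks: tuple = ()
    redundancy: dict = field(default_factory=dict)  # item -> (source, flip_p)
    seed: int = 0

    def __post_init__(self):
        p = sum(n for _, n in self.domains)
        if len(self.discrimination) != p or len(self.difficulty) != p:
            raise ValueError("item parameters must cover every item")
        if any(a < 0 for a in self.discrimination):
            raise ValueError("discrimination must be non-negative")
        if not 0.0 <= self.hospital_fraction <= 1.0:
            raise ValueError("hospital_fraction must be in [0, 1]")
        if abs(sum(c.share for c in self.countries) - 1.0) > 1e-9:
            raise ValueError("country shares must sum to 1")
        known = set(self.item_ids)
        for blk in self.service_blocks:
            unknown = set(blk.item_ids) - known
            if unknown:
                raise ValueError(f"service block {blk.name} gates unknown "
                                 f"items {sorted(unknown)}")
        for tgt, (src, flip) in self.redundancy.items():
            if tgt not in known or src not in known:
                raise ValueError("redundancy must reference existing items")
            if not 0.0 <= flip <= 1.0:
                raise ValueError("flip probability must be in [0, 1]")

    @property
    def item_ids(self) -> tuple:
        return tuple(
            f"{dom}_{i:02d}" for dom, n in self.domains for i in range(n)
        )

    @property
    def n_items(self) -> int:
        return sum(n for _, n in self.domains)

    @property
    def n_noise_items(self) -> int:
        return int(sum(1 for a in self.discrimination if a == 0))

    def domain_map(self) -> DomainMap:
        assignment = {
            f"{dom}_{i:02d}": dom for dom, n in self.domains for i in range(n)
        }
        return DomainMap(assignment=assignment,
                         domains=tuple(d for d, _ in self.domains))


@dataclass(frozen=True)
class SyntheticTruth:
    """Latent state stored with every generated matrix for recovery tests."""

    theta: np.ndarray
    hospital: np.ndarray
    service_offered: dict            # block name -> bool array per facility
    discrimination: np.ndarray
    difficulty: np.ndarray
    item_ids: tuple

    @property
    def informative_items(self) -> tuple:
        """Items with high discrimination (a >= 2)."""
        return tuple(
            i for i, a in zip(self.item_ids, self.discrimination) if a >= 2.0
        )

    @property
    def noise_items(self) -> tuple:
        return tuple(
            i for i, a in zip(self.item_ids, self.discrimination) if a == 0.0
        )


def generate(config: GeneratorConfig):
    """Draw one (ItemMatrix, SyntheticTruth) pair, reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_facilities
    item_ids = config.item_ids
    p = len(item_ids)

    shares = np.array([c.share for c in config.countries])
    counts = np.floor(shares * n).astype(int)
    counts[: n - counts.sum()] += 1  # largest strata absorb the remainder
    country = np.repeat([c.name for c in config.countries], counts)
    offset = np.repeat([c.mean_offset for c in config.countries], counts)
    wscale = np.repeat([c.weight_scale for c in config.countries], counts)

    hospital = rng.random(n) < config.hospital_fraction
    theta = offset + config.hospital_bonus * hospital + rng.standard_normal(n)

    a = np.asarray(config.discrimination, dtype=float)
    b = np.asarray(config.difficulty, dtype=float)
    prob = expit(a * (theta[:, None] - b))
    x = (rng.random((n, p)) < prob).astype(np.int8)

    col_of = {iid: j for j, iid in enumerate(item_ids)}
    offered = {}
    for blk in config.service_blocks:
        ind = rng.random(n) < blk.offer_prob
        cols = [col_of[i] for i in blk.item_ids]
        x[np.ix_(~ind, cols)] = 0
        offered[blk.name] = ind

    for tgt, (src, flip) in sorted(config.redundancy.items()):
        flips = rng.random(n) < flip
        x[:, col_of[tgt]] = np.where(
            flips, 1 - x[:, col_of[src]], x[:, col_of[src]]
        )

    weight = wscale * rng.uniform(0.5, 1.5, n)
    matrix = ItemMatrix(
        facility_ids=np.array([f"F{i:05d}" for i in range(n)]),
        country=country,
        facility_type=np.where(hospital, "hospital", "non-hospital"),
        weight=weight,
        item_ids=item_ids,
        items=x,
    )
    truth = SyntheticTruth(
        theta=theta,
        hospital=hospital,
        service_offered=offered,
        discrimination=a,
        difficulty=b,
        item_ids=item_ids,
    )
    return matrix, truth


BENCHMARK_SEED = 20180

_DOMAIN_NAMES = (
    "amenities",
    "equipment",
    "infection_prevention",
    "diagnostics",
    "medication",
    "management",
)

# (n_items, n_informative, n_gated) per domain; the remainder are noise.
# Four compact core domains carry the 12 high-discrimination items; the two
# large catch-all domains hold the weakly informative bulk, the way breadth
# domains (medication stock, management records) do in real assessments.
_BENCHMARK_LAYOUT = (
    ("amenities", 3, 3, 0),
    ("equipment", 3, 3, 0),
    ("infection_prevention", 4, 3, 0),
    ("diagnostics", 6, 3, 0),
    ("medication", 21, 0, 3),
    ("management", 23, 0, 3),
)


def benchmark_config(seed: int = BENCHMARK_SEED) -> GeneratorConfig:
    """The packaged 800-facility, 60-item benchmark.

    Twelve high-discrimination items (a = 2.5) with difficulties spread over
    the readiness range sit in the four core domains, three per domain, so
    each carries ranking information about a distinct readiness slice. The
    two large domains contribute 6 service-gated items (a = 1.0, service
    offered by 70% of facilities) and 42 zero-discrimination noise items.
    Four country strata with distinct mean readiness and weight scales; 20%
    of facilities are hospitals with a +1 readiness bonus.
    """
    n_inf_total = sum(ninf for _, _, ninf, _ in _BENCHMARK_LAYOUT)
    spread = np.linspace(-1.2, 1.2, n_inf_total) + 0.15
    # stride-5 interleave: consecutive items within a domain get difficulties
    # from different parts of the range
    thresholds = [spread[(i * 5) % n_inf_total] for i in range(n_inf_total)]
    domains = tuple((d, n) for d, n, _, _ in _BENCHMARK_LAYOUT)
    a, b = [], []
    blocks = []
    bi = 0
    for dom, nd, ninf, ngate in _BENCHMARK_LAYOUT:
        for _ in range(ninf):
            a.append(2.5)
            b.append(float(thresholds[bi]))
            bi += 1
        for g in range(ngate):
            a.append(1.0)
            b.append(0.0 if g % 2 == 0 else 0.4)
        a.extend([0.0] * (nd - ninf - ngate))
        b.extend([0.0] * (nd - ninf - ngate))
        if ngate:
            blocks.append(
                ServiceBlock(
                    name=f"svc_{dom}",
                    item_ids=tuple(
                        f"{dom}_{j:02d}" for j in range(ninf, ninf + ngate)
                    ),
                    offer_prob=0.7,
                )
            )
    countries = (
        CountrySpec("alphaland", -0.5, 1.0, 0.30),
        CountrySpec("bravia", -0.15, 1.4, 0.30),
        CountrySpec("carmona", 0.2, 0.8, 0.25),
        CountrySpec("deltora", 0.6, 1.2, 0.15),
    )
    return GeneratorConfig(
        n_facilities=800,
        countries=countries,
        hospital_fraction=0.2,
        hospital_bonus=1.0,
        domains=domains,
        discrimination=tuple(a),
        difficulty=tuple(b),
        service_blocks=tuple(blocks),
        seed=seed,
    )


@lru_cache(maxsize=1)
def benchmark_fixture():
    """The fixed-seed benchmark matrix used by regression tests (cached)."""
    return generate(benchmark_config())


def sri_like_items() -> tuple:
    """An expert-core stand-in for the benchmark: 10 locked items.

    Mirrors how a normative index covers five of the six domains (no
    management items) and mixes genuinely informative items with weak,
    gated and noise ones.
    """
    return (
        "amenities_00", "amenities_01",            # informative
        "equipment_00", "equipment_01",            # informative
        "infection_prevention_00",                 # informative
        "infection_prevention_03",                 # noise
        "diagnostics_00",                          # informative
        "diagnostics_04",                          # noise
        "medication_00",                           # gated
        "medication_05",                           # noise
    )
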