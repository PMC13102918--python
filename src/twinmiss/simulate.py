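"""Twin-data simulators with known ACE structure.

The classical twin design decomposes trait variance into additive genetics
(A), shared environment (C), and unique environment (E).  The generating
model for twin j of a pair is::

    y_j = mean + sd * (a * A_j + c * C + e * E_j),   a = sqrt(a2), ...

where A is shared perfectly within MZ pairs and correlated 0.5 within DZ
pairs (the classical assumption for segregating DNA), C is shared within
every pair, and E is twin-specific.  Expected within-pair correlations are
therefore ``a2 + c2`` (MZ) and ``0.5 * a2 + c2`` (DZ).

Binary traits arise by dichotomising a latent standard-normal liability at
the threshold ``tau = Phi^-1(1 - prevalence)``: outcome 1 (e.g. "data
missing") iff liability > tau.

Randomness uses one master seed with per-pair substreams derived through
``numpy.random.SeedSequence.spawn``, so increasing the pair count never
reshuffles earlier pairs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import ABSENT, DZ, MZ, TraitSpec, TwinDataset
from .exceptions import SpecError

__all__ = [
    "SimulationSpec",
    "simulate_continuous",
    "simulate_binary_liability",
    "simulate_bivariate",
]

_DZ_GENETIC_R = 0.5  # DZ twins share on average half the segregating DNA


@dataclass(frozen=True)
class SimulationSpec:
    """Generating truth for one simulated trait.

    ``a2 + c2 + e2`` must equal 1; for binary traits ``prevalence`` is the
    marginal probability of outcome 1, for continuous traits ``mean``/``sd``
    locate and scale the trait.  ``missing_rate`` independently blanks each
    twin's value.
    """

    a2: float
    c2: float
    e2: float
    n_mz_pairs: int
    n_dz_pairs: int
    trait_kind: str = "continuous"
    prevalence: float | None = None
    mean: float = 0.0
    sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0
    trait_name: str = "trait"

    def __post_init__(self):
        self.validate()

    def validate(self):
        shares = (self.a2, self.c2, self.e2)
        if any(s < 0 for s in shares):
            raise SpecError(f"variance shares must be non-negative, got {shares}")
        if abs(sum(shares) - 1.0) > 1e-9:
            raise SpecError(f"a2 + c2 + e2 = {sum(shares)!r}, must be 1")
        if self.trait_kind not in ("continuous", "binary"):
            raise SpecError(f"unknown trait_kind {self.trait_kind!r}")
        if self.trait_kind == "binary":
            if self.prevalence is None or not 0.0 < self.prevalence < 1.0:
                raise SpecError("binary traits need prevalence strictly in (0, 1)")
        if self.sd <= 0:
            raise SpecError("sd must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SpecError("missing_rate must be in [0, 1)")
        if self.n_mz_pairs < 0 or self.n_dz_pairs < 0:
            raise SpecError("pair counts must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        return cls(**d)

    def trait_spec(self) -> TraitSpec:
        if self.trait_kind == "binary":
            return TraitSpec(self.trait_name, "binary")
        return TraitSpec(self.trait_name, "continuous", valid_range=None)


def _pair_streams(seed: int, n: int):
    root = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in root.spawn(n)]


def _latent_pair(rng, zygosity: str, a: float, c: float, e: float):
    """One pair of standardised latent trait values (variance 1 each)."""
    g1, g2, cc, e1, e2 = rng.standard_normal(5)
    if zygosity == MZ:
        a1 = a2_ = g1
    else:
        a1 = g1
        a2_ = _DZ_GENETIC_R * g1 + np.sqrt(1.0 - _DZ_GENETIC_R**2) * g2
    y1 = a * a1 + c * cc + e * e1
    y2 = a * a2_ + c * cc + e * e2
    return y1, y2, rng.random(2)


def _assemble(spec: SimulationSpec, transform) -> TwinDataset:
    a, c, e = np.sqrt([spec.a2, spec.c2, spec.e2])
    n = spec.n_mz_pairs + spec.n_dz_pairs
    streams = _pair_streams(spec.seed, n)
    rows = []
    for i in range(n):
        zyg = MZ if i < spec.n_mz_pairs else DZ
        y1, y2, u = _latent_pair(streams[i], zyg, a, c, e)
        v1, v2 = transform(y1), transform(y2)
        if u[0] < spec.missing_rate:
            v1 = ABSENT
        if u[1] < spec.missing_rate:
            v2 = ABSENT
        rows.append(
            {
                "pair_id": f"pair{i:06d}",
                "zygosity": zyg,
                f"{spec.trait_name}_t1": v1,
                f"{spec.trait_name}_t2": v2,
            }
        )
    frame = pd.DataFrame(rows)
    return TwinDataset.from_frame(frame, [spec.trait_spec()])


def simulate_continuous(spec: SimulationSpec) -> TwinDataset:
    """Simulate a continuous ACE trait; see module docstring for the model."""
    if spec.trait_kind != "continuous":
        raise SpecError("simulate_continuous requires trait_kind='continuous'")
    return _assemble(spec, lambda y: spec.mean + spec.sd * y)


def simulate_binary_liability(spec: SimulationSpec) -> TwinDataset:
    """Simulate a binary trait via the liability-threshold mechanism."""
    if spec.trait_kind != "binary":
        raise SpecError("simulate_binary_liability requires trait_kind='binary'")
    tau = norm.ppf(1.0 - spec.prevalence)
    return _assemble(spec, lambda y: 1.0 if y > tau else 0.0)


def simulate_bivariate(
    spec_x: SimulationSpec,
    spec_y: SimulationSpec,
    r_pheno: float,
    n_mz_pairs: int,
    n_dz_pairs: int,
    seed: int,
) -> TwinDataset:
    """Simulate two continuous traits with a chosen within-person correlation.

    The traits' unique-environment components are correlated so that the
    within-person cross-trait correlation converges to ``r_pheno``; A and C
    are trait-independent, so cross-twin cross-trait correlations are zero
    by construction.  This requires ``|r_pheno| <= sqrt(e2_X * e2_Y)``.
    """
    for s in (spec_x, spec_y):
        if s.trait_kind != "continuous":
            raise SpecError("simulate_bivariate requires continuous specs")
    if spec_x.trait_name == spec_y.trait_name:
        raise SpecError("the two traits must have distinct names")
    bound = np.sqrt(spec_x.e2 * spec_y.e2)
    if abs(r_pheno) > bound + 1e-12:
        raise SpecError(
            f"|r_pheno| = {abs(r_pheno)} exceeds the achievable bound "
            f"sqrt(e2_X * e2_Y) = {bound:.6f} under E-coupled construction"
        )
    rho_e = 0.0 if bound == 0 else r_pheno / (spec_x.e2 * spec_y.e2) ** 0.5

    ax, cx, ex = np.sqrt([spec_x.a2, spec_x.c2, spec_x.e2])
    ay, cy, ey = np.sqrt([spec_y.a2, spec_y.c2, spec_y.e2])
    comp = np.sqrt(max(0.0, 1.0 - rho_e**2))
    n = n_mz_pairs + n_dz_pairs
    streams = _pair_streams(seed, n)
    rows = []
    for i in range(n):
        zyg = MZ if i < n_mz_pairs else DZ
        rng = streams[i]
        gx1, gx2, ccx, gy1, gy2, ccy = rng.standard_normal(6)
        ze = rng.standard_normal((2, 2))  # twin x (primary, orthogonal)
        if zyg == MZ:
            axx = (gx1, gx1)
            ayy = (gy1, gy1)
        else:
            axx = (gx1, _DZ_GENETIC_R * gx1 + np.sqrt(0.75) * gx2)
            ayy = (gy1, _DZ_GENETIC_R * gy1 + np.sqrt(0.75) * gy2)
        row = {"pair_id": f"pair{i:06d}", "zygosity": zyg}
        u = rng.random(4)
        for j in (0, 1):
            e_x = ze[j, 0]
            e_y = rho_e * ze[j, 0] + comp * ze[j, 1]
            vx = spec_x.mean + spec_x.sd * (ax * axx[j] + cx * ccx + ex * e_x)
            vy = spec_y.mean + spec_y.sd * (ay * ayy[j] + cy * ccy + ey * e_y)
            if u[2 * j] < spec_x.missing_rate:
                vx = ABSENT
            if u[2 * j + 1] < spec_y.missing_rate:
                vy = ABSENT
            row[f"{spec_x.trait_name}_t{j + 1}"] = vx
            row[f"{spec_y.trait_name}_t{j + 1}"] = vy
        rows.append(row)
    frame = pd.DataFrame(rows)
    return TwinDataset.from_frame(frame, [spec_x.trait_spec(), spec_y.trait_spec()])
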