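"""Synthetic binary-mixture datasets with known ground truth.

Real mixture-property collections (densities, bubble temperatures, azeotrope
labels) are not redistributable, so tests and calibration runs use a
generator that reproduces their statistical *shape* while keeping the data
generating process fully known:

* compounds carry i.i.d. standard-normal descriptor vectors ``d_i`` and a
  latent pure-compound property ``p_i = w . d_i + c_i``, where ``w`` is the
  additive weight vector and ``c_i ~ N(0, sigma_c^2)`` a compound-specific
  effect invisible to the descriptors (what makes compounds-out hard);
* a random subset of compound pairs is realized as mixtures; each mixture is
  measured on an even composition grid in (0.5, 1);
* the observed value is the ideal (linearly mixed) part plus a non-additive
  pair interaction scaled by ``gamma * x1 * x2`` plus measurement noise.

Endpoints:

``bubble_like``         — the observed value itself (composition-dependent);
``density_deviation``   — observation minus the ideal part, i.e. the excess
                          quantity a deviation-from-ideality model targets;
``azeotrope_label``     — one binary label per mixture: positive when the
                          pair's interaction score exceeds the sample median
                          (exactly balanced classes), pure compounds labeled
                          zeotrope.

Everything is deterministic given ``seed``. No thermodynamics is simulated;
the generator provides statistical structure, not physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .component_descriptors import DescriptorMatrix
from .errors import ConfigError, DomainError
from .mixture_data import (
    AZEOTROPE,
    ZEOTROPE,
    CompoundRef,
    MixtureDataset,
    MixtureRecord,
)

ENDPOINTS = ("density_deviation", "bubble_like", "azeotrope_label")


def ideal_mixture_value(p_i: float, p_j: float, x1: float) -> float:
    """Ideal (additive) mixture value: mole-fraction-linear combination.

    The baseline against which non-additivity is defined; the deviation
    endpoint stores observation minus this quantity.
    """
    if not (0.5 <= x1 <= 1.0):
        raise DomainError(f"x1 must lie in [0.5, 1], got {x1}")
    return x1 * p_i + (1.0 - x1) * p_j


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study.

    ``pair_density`` is the fraction of all C(n, 2) unordered pairs realized
    as mixtures; ``n_pairs`` may be given instead for an exact count.
    ``interaction_strength`` (gamma) scales the non-additive pair term and
    ``compound_effect_sd`` (sigma_c) the descriptor-invisible per-compound
    effect; both at 0 give a perfectly additive, descriptor-explainable
    property.
    """

    n_compounds: int = 60
    m_descriptors: int = 8
    compositions_per_mixture: int = 9
    pair_density: float = 0.1
    n_pairs: Optional[int] = None
    additive_weights: Optional[np.ndarray] = None  # default: rng standard normal
    interaction_strength: float = 0.0
    compound_effect_sd: float = 0.0
    noise_sd: float = 0.0
    endpoint: str = "bubble_like"
    include_pure: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ConfigError(f"unknown endpoint: {self.endpoint!r}")
        if self.n_compounds < 2 or self.m_descriptors < 1:
            raise ConfigError("need at least 2 compounds and 1 descriptor")
        if not (0.0 < self.pair_density <= 1.0):
            raise ConfigError(f"pair_density must lie in (0, 1], got {self.pair_density}")
        if self.compositions_per_mixture < 1:
            raise ConfigError("compositions_per_mixture must be >= 1")
        for name in ("interaction_strength", "compound_effect_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.endpoint == "azeotrope_label":
            # one label per mixture: composition is irrelevant
            object.__setattr__(self, "compositions_per_mixture", 1)

    def resolved_n_pairs(self) -> int:
        total = self.n_compounds * (self.n_compounds - 1) // 2
        n = self.n_pairs if self.n_pairs is not None else round(self.pair_density * total)
        if n < 1:
            raise ConfigError("pair_density too low: no pair realized")
        if n > total:
            raise ConfigError(f"requested {n} pairs but only {total} exist")
        return n


def _compound_name(i: int) -> str:
    return f"SYN-{i:04d}"


def generate_compounds(spec: SyntheticSpec) -> tuple[DescriptorMatrix, dict[CompoundRef, float]]:
    """Draw compound descriptor vectors and latent pure property values.

    Descriptors are i.i.d. N(0, 1); the pure value of compound i is
    ``w . d_i + c_i`` with ``c_i ~ N(0, sigma_c^2)``, so its theoretical
    standard deviation over compounds is sqrt(|w|^2 + sigma_c^2).
    """
    matrix, pure_values, _, _ = _generate_compounds_full(spec)
    return matrix, pure_values


def _generate_compounds_full(
    spec: SyntheticSpec,
) -> tuple[DescriptorMatrix, dict[CompoundRef, float], np.ndarray, np.ndarray]:
    rng = np.random.default_rng(spec.seed)
    D = rng.standard_normal((spec.n_compounds, spec.m_descriptors))
    w = (
        np.asarray(spec.additive_weights, dtype=float)
        if spec.additive_weights is not None
        else rng.standard_normal(spec.m_descriptors)
    )
    if w.shape != (spec.m_descriptors,):
        raise ConfigError("additive_weights must have length m_descriptors")
    c = rng.normal(0.0, spec.compound_effect_sd, size=spec.n_compounds)
    p = D @ w + c

    compounds = [CompoundRef(_compound_name(i)) for i in range(spec.n_compounds)]
    matrix = DescriptorMatrix(
        descriptor_names=[f"d{j}" for j in range(spec.m_descriptors)],
        rows={compounds[i]: D[i] for i in range(spec.n_compounds)},
        backend_id="synthetic",
    )
    pure_values = {compounds[i]: float(p[i]) for i in range(spec.n_compounds)}
    return matrix, pure_values, w, c


def _sample_pairs(n_compounds: int, n_pairs: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Sample pairs without replacement, then repair so every compound is covered.

    With enough pairs (>= n/2) the repair swaps pairs of over-represented
    compounds for pairs touching uncovered ones, keeping the count exact; it
    makes downstream pure-compound augmentation counts deterministic.
    """
    all_pairs = [(i, j) for i in range(n_compounds) for j in range(i + 1, n_compounds)]
    order = rng.permutation(len(all_pairs))
    chosen = [all_pairs[i] for i in order[:n_pairs]]
    if n_pairs * 2 < n_compounds:
        return chosen  # full coverage impossible; leave as sampled

    remaining = [all_pairs[i] for i in order[n_pairs:]]
    degree = np.zeros(n_compounds, dtype=int)
    for a, b in chosen:
        degree[a] += 1
        degree[b] += 1
    uncovered = [i for i in range(n_compounds) if degree[i] == 0]
    for u in uncovered:
        # bring in a pair touching u, drop a pair whose ends stay covered
        incoming = next(p for p in remaining if u in p)
        for pos in range(len(chosen) - 1, -1, -1):
            a, b = chosen[pos]
            if degree[a] > 1 and degree[b] > 1:
                degree[a] -= 1
                degree[b] -= 1
                chosen[pos] = incoming
                degree[incoming[0]] += 1
                degree[incoming[1]] += 1
                remaining.remove(incoming)
                break
        else:
            raise ConfigError("could not repair pair coverage; increase n_pairs")
    return chosen


def _composition_grid(n: int) -> np.ndarray:
    """Even grid of majority fractions strictly inside (0.5, 1).

    Endpoints are excluded: x1 = 1 is the pure record and x1 = 0.5 would need
    the equimolar tie-break; an interior grid keeps mixture records distinct
    from both."""
    return 0.5 + 0.5 * (np.arange(1, n + 1) / (n + 1))


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset, for parameter-recovery checks."""

    additive_weights: np.ndarray
    pure_values: dict[CompoundRef, float]
    compound_effects: dict[CompoundRef, float] = field(default_factory=dict)
    interaction_scores: dict[tuple[str, str], float] = field(default_factory=dict)
    label_threshold: float | None = None


def generate_mixture_dataset(spec: SyntheticSpec) -> tuple[MixtureDataset, DescriptorMatrix, SyntheticTruth]:
    """Generate a full synthetic study: dataset, descriptor matrix, ground truth.

    Regression observation for pair (i, j) at majority fraction x1:
    ``x1*p_i + x2*p_j + gamma*x1*x2*g_ij + eps``, with the pair interaction
    ``g_ij = u . (d_i * d_j) + b * (v . |d_i - d_j|)`` for fixed random
    u, v, b drawn once per seed. The azeotrope label is positive when
    ``gamma * g_ij`` exceeds the empirical median over the realized pairs, so
    the generated classes are balanced exactly (the threshold is the fixed
    point a bisection on the realized sample would converge to).
    """
    matrix, pure_values, w, c_effects = _generate_compounds_full(spec)
    rng = np.random.default_rng(spec.seed + 1)  # independent of compound draw

    compounds = [CompoundRef(_compound_name(i)) for i in range(spec.n_compounds)]
    pairs = _sample_pairs(spec.n_compounds, spec.resolved_n_pairs(), rng)

    u = rng.standard_normal(spec.m_descriptors)
    v = rng.standard_normal(spec.m_descriptors)
    b = float(rng.standard_normal())

    def interaction(i: int, j: int) -> float:
        di, dj = matrix.rows[compounds[i]], matrix.rows[compounds[j]]
        return float(u @ (di * dj) + b * (v @ np.abs(di - dj)))

    g = {pr: interaction(*pr) for pr in pairs}
    truth = SyntheticTruth(
        additive_weights=w,
        pure_values=pure_values,
        compound_effects={compounds[i]: float(c_effects[i]) for i in range(spec.n_compounds)},
        interaction_scores={
            (compounds[i].structure, compounds[j].structure): gv for (i, j), gv in g.items()
        },
    )

    records: list[MixtureRecord] = []
    prop = spec.endpoint
    if spec.endpoint == "azeotrope_label":
        scores = np.asarray([spec.interaction_strength * g[pr] for pr in pairs])
        threshold = float(np.median(scores))
        truth.label_threshold = threshold
        for pr, score in zip(pairs, scores):
            i, j = pr
            label = AZEOTROPE if score > threshold else ZEOTROPE
            c1, c2 = sorted((compounds[i], compounds[j]))
            records.append(MixtureRecord(c1, c2, 0.5, prop, label))
        if spec.include_pure:
            for c in _covered(compounds, pairs):
                records.append(MixtureRecord(c, None, 1.0, prop, ZEOTROPE))
        dataset = MixtureDataset(
            records=records,
            property=prop,
            endpoint_kind="classification",
            concentration_dependent=False,
        )
        return dataset, matrix, truth

    grid = _composition_grid(spec.compositions_per_mixture)
    for pr in pairs:
        i, j = pr
        p_i, p_j = pure_values[compounds[i]], pure_values[compounds[j]]
        for x1 in grid:
            x1 = float(x1)
            x2 = 1.0 - x1
            ideal = ideal_mixture_value(p_i, p_j, x1)
            eps = float(rng.normal(0.0, spec.noise_sd)) if spec.noise_sd > 0 else 0.0
            observed = ideal + spec.interaction_strength * x1 * x2 * g[pr] + eps
            value = observed - ideal if spec.endpoint == "density_deviation" else observed
            records.append(MixtureRecord(compounds[i], compounds[j], x1, prop, value))
    if spec.include_pure:
        for c in _covered(compounds, pairs):
            value = 0.0 if spec.endpoint == "density_deviation" else pure_values[c]
            records.append(MixtureRecord(c, None, 1.0, prop, value))

    dataset = MixtureDataset(
        records=records,
        property=prop,
        endpoint_kind="regression",
        concentration_dependent=True,
    )
    return dataset, matrix, truth


def _covered(compounds: list[CompoundRef], pairs: list[tuple[int, int]]) -> list[CompoundRef]:
    seen: dict[int, None] = {}
    for i, j in pairs:
        seen.setdefault(i, None)
        seen.setdefault(j, None)
    return [compounds[i] for i in sorted(seen)]
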