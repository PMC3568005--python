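"""Mixture feature vectors built from component descriptor vectors.

Four construction schemes, split by whether the endpoint depends on
composition. With D1, D2 the component descriptor vectors and x1, x2 = 1 - x1
the molar fractions (x1 >= 0.5 by the storage convention):

concentration-independent endpoints (one value per mixture):

* ``AVERAGE``       — (D1 + D2) / 2                          (m features)
* ``SUM_ABSDIFF``   — [D1 + D2, |D1 - D2|]                   (2m features)

concentration-dependent endpoints (one value per composition):

* ``WEIGHTED_SUM``          — x1*D1 + x2*D2                  (m features)
* ``WEIGHTED_SUM_ABSDIFF``  — [x1*D1 + x2*D2, |x1*D1 - x2*D2|]  (2m)

All four are symmetric under relabeling the components ((A, x) vs (B, 1-x)),
so together with record canonicalization the feature row of a mixture does
not depend on how it was uploaded. Pure compounds are degenerate mixtures of
themselves: weighted schemes at x1 = 1 reduce to the compound's own vector,
and unweighted schemes use D1 = D2 so the difference block vanishes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .component_descriptors import DescriptorMatrix
from .errors import ConfigError, CoverageError, DimensionError, DomainError
from .mixture_data import MixtureDataset

SCHEMES = ("AVERAGE", "SUM_ABSDIFF", "WEIGHTED_SUM", "WEIGHTED_SUM_ABSDIFF")
WEIGHTED_SCHEMES = ("WEIGHTED_SUM", "WEIGHTED_SUM_ABSDIFF")


def _check_lengths(D1: np.ndarray, D2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    D1 = np.asarray(D1, dtype=float)
    D2 = np.asarray(D2, dtype=float)
    if D1.shape != D2.shape:
        raise DimensionError(f"component vectors differ in shape: {D1.shape} vs {D2.shape}")
    return D1, D2


def mix_average(D1: np.ndarray, D2: np.ndarray) -> np.ndarray:
    """Unweighted elementwise average of the component vectors."""
    D1, D2 = _check_lengths(D1, D2)
    return (D1 + D2) / 2.0


def mix_sum_absdiff(D1: np.ndarray, D2: np.ndarray) -> np.ndarray:
    """Concatenated elementwise sum and absolute difference (2m features)."""
    D1, D2 = _check_lengths(D1, D2)
    return np.concatenate([D1 + D2, np.abs(D1 - D2)])


def _check_x1(x1: float) -> float:
    x1 = float(x1)
    if not (0.5 <= x1 <= 1.0):
        raise DomainError(f"x1 must lie in [0.5, 1], got {x1}")
    return x1


def mix_weighted_sum(D1: np.ndarray, D2: np.ndarray, x1: float) -> np.ndarray:
    """Mole-fraction-weighted sum x1*D1 + (1-x1)*D2."""
    D1, D2 = _check_lengths(D1, D2)
    x1 = _check_x1(x1)
    return x1 * D1 + (1.0 - x1) * D2


def mix_weighted_sum_absdiff(D1: np.ndarray, D2: np.ndarray, x1: float) -> np.ndarray:
    """Concatenated weighted sum and weighted absolute difference (2m).

    The difference block is |x1*D1 - x2*D2| (weight-then-difference), the form
    that generalizes the mole-weighted fragment-count construction this family
    of descriptors descends from.
    """
    D1, D2 = _check_lengths(D1, D2)
    x1 = _check_x1(x1)
    x2 = 1.0 - x1
    return np.concatenate([x1 * D1 + x2 * D2, np.abs(x1 * D1 - x2 * D2)])


_SUFFIXES = {
    "AVERAGE": (("_avg",),),
    "SUM_ABSDIFF": (("_sum",), ("_absdiff",)),
    "WEIGHTED_SUM": (("_wsum",),),
    "WEIGHTED_SUM_ABSDIFF": (("_wsum",), ("_wabsdiff",)),
}


def feature_names(descriptor_names: list[str], scheme: str) -> list[str]:
    """Deterministic feature-name grammar for a scheme."""
    if scheme not in SCHEMES:
        raise ConfigError(f"unknown scheme: {scheme!r}")
    out: list[str] = []
    for block in _SUFFIXES[scheme]:
        out.extend(n + block[0] for n in descriptor_names)
    return out


@dataclass
class MixtureFeatureTable:
    """Per-record feature rows aligned with target values.

    ``record_keys`` are record indices into the originating dataset, in the
    same order as the rows of ``X`` and entries of ``y``.
    """

    scheme: str
    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray
    record_keys: list[int]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.shape[0] != len(self.record_keys) or len(self.y) != len(self.record_keys):
            raise ConfigError("X, y and record_keys must agree in length")
        if self.X.shape[1] != len(self.feature_names):
            raise ConfigError("X width must match feature_names")


def mixture_features(D1: np.ndarray, D2: np.ndarray, x1: float, scheme: str) -> np.ndarray:
    """Feature vector of one mixture under the named scheme."""
    if scheme == "AVERAGE":
        return mix_average(D1, D2)
    if scheme == "SUM_ABSDIFF":
        return mix_sum_absdiff(D1, D2)
    if scheme == "WEIGHTED_SUM":
        return mix_weighted_sum(D1, D2, x1)
    if scheme == "WEIGHTED_SUM_ABSDIFF":
        return mix_weighted_sum_absdiff(D1, D2, x1)
    raise ConfigError(f"unknown scheme: {scheme!r}")


def featurize_dataset(
    dataset: MixtureDataset,
    matrix: DescriptorMatrix,
    scheme: str,
) -> MixtureFeatureTable:
    """Build the feature table of a dataset under one scheme.

    Pure records are featurized consistently with the pure-compound limit:
    weighted schemes use D2 = 0 and x1 = 1 (the x2-weighted terms vanish, so
    the row equals the compound's own vector with a zero difference block);
    unweighted schemes use D1 = D2 = the compound's vector, so the sum block
    doubles and the difference block is zero.

    Scheme/endpoint pairing is advisory: weighted schemes on a
    concentration-independent dataset (or vice versa) emit a warning but are
    not forbidden.
    """
    if scheme not in SCHEMES:
        raise ConfigError(f"unknown scheme: {scheme!r}")
    uncovered = matrix.covers(dataset.compounds())
    if uncovered:
        raise CoverageError(
            "descriptor matrix lacks compounds: " + ", ".join(c.structure for c in uncovered)
        )
    weighted = scheme in WEIGHTED_SCHEMES
    if weighted and not dataset.concentration_dependent:
        warnings.warn(
            f"{scheme} is intended for concentration-dependent endpoints; this dataset "
            "carries one value per mixture", stacklevel=2,
        )
    if not weighted and dataset.concentration_dependent:
        warnings.warn(
            f"{scheme} ignores composition; this dataset has several values per mixture",
            stacklevel=2,
        )

    m = matrix.n_descriptors
    zero = np.zeros(m)
    rows: list[np.ndarray] = []
    for r in dataset.records:
        D1 = matrix.vector(r.component1)
        if r.is_pure:
            D2 = zero if weighted else D1
            x1 = 1.0
        else:
            D2 = matrix.vector(r.component2)
            x1 = r.x1
        rows.append(mixture_features(D1, D2, x1, scheme))

    y = np.asarray([r.value for r in dataset.records], dtype=float)
    return MixtureFeatureTable(
        scheme=scheme,
        feature_names=feature_names(matrix.descriptor_names, scheme),
        X=np.vstack(rows),
        y=y,
        record_keys=list(range(len(dataset.records))),
    )
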