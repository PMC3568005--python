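"""Per-compound descriptor matrices behind a pluggable backend contract.

A descriptor backend maps a canonical structure string to a named vector of
floats, deterministically. The published mixture-QSPR studies use commercial
engines (Dragon, ChemAxon, Adriana, inductive descriptors); those are not
reimplemented here. Instead the package ships:

* :class:`RDKitDescriptorBackend` — an open-toolkit 2D physicochemical /
  topological set (no 3D conformer dependence, fully deterministic);
* :class:`DictBackend` — wraps any precomputed mapping structure -> vector,
  used for descriptor cache files and synthetic data;
* :func:`toy_backend` — a tiny deterministic backend for tests.

Assembled matrices drop constant columns (no information) and columns with
any non-finite value (QSPR convention: drop, do not impute, so folds stay
comparable).
"""

from __future__ import annotations

import logging
from collections.abc import Callable, Iterable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import BackendError, ConfigError, SelectionError
from .mixture_data import CompoundRef

logger = logging.getLogger(__name__)

# backend contract: canonical structure -> (descriptor names, values)
DescriptorBackend = Callable[[str], tuple[Sequence[str], Sequence[float]]]


@dataclass
class DescriptorMatrix:
    """Descriptor vectors for a set of compounds with a shared column list."""

    descriptor_names: list[str]
    rows: dict[CompoundRef, np.ndarray]
    backend_id: str = ""

    def __post_init__(self) -> None:
        if len(set(self.descriptor_names)) != len(self.descriptor_names):
            raise ConfigError("descriptor names must be unique")
        m = len(self.descriptor_names)
        for c, v in self.rows.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (m,):
                raise ConfigError(
                    f"vector for {c.structure} has length {v.shape}, expected ({m},)"
                )
            self.rows[c] = v

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptor_names)

    def vector(self, compound: CompoundRef) -> np.ndarray:
        return self.rows[compound]

    def covers(self, compounds: Iterable[CompoundRef]) -> list[CompoundRef]:
        """Compounds from ``compounds`` NOT covered by this matrix."""
        return [c for c in compounds if c not in self.rows]

    def select(self, names: Sequence[str]) -> "DescriptorMatrix":
        """Restrict to the named columns, in the order given."""
        missing = [n for n in names if n not in self.descriptor_names]
        if missing:
            raise SelectionError(f"unknown descriptor name(s): {', '.join(missing)}")
        idx = [self.descriptor_names.index(n) for n in names]
        return DescriptorMatrix(
            descriptor_names=list(names),
            rows={c: v[idx] for c, v in self.rows.items()},
            backend_id=self.backend_id,
        )

    def to_frame(self) -> pd.DataFrame:
        structures = sorted(c.structure for c in self.rows)
        by_struct = {c.structure: v for c, v in self.rows.items()}
        data = np.array([by_struct[s] for s in structures]) if structures else np.empty((0, 0))
        df = pd.DataFrame(data, columns=self.descriptor_names)
        df.insert(0, "structure", structures)
        return df


def compute_matrix(
    compounds: Iterable[CompoundRef],
    backend: DescriptorBackend,
    backend_id: str = "",
    select: Sequence[str] | None = None,
) -> DescriptorMatrix:
    """Compute a descriptor matrix for a compound set.

    Constant columns are dropped; columns containing any non-finite value are
    dropped with a warning. ``select`` restricts the surviving columns by
    name (applied after computation, so the drop rules see all columns).
    Backend failures are gathered and reported together, naming each failing
    compound.
    """
    compounds = sorted(set(compounds))  # permutation invariance
    if not compounds:
        raise ConfigError("empty compound set")

    names: list[str] | None = None
    vectors: list[np.ndarray] = []
    failures: list[str] = []
    for c in compounds:
        try:
            cnames, values = backend(c.structure)
        except Exception as e:  # noqa: BLE001 - aggregated below
            failures.append(f"{c.structure}: {e}")
            continue
        if names is None:
            names = list(cnames)
        elif list(cnames) != names:
            raise BackendError(
                f"backend returned inconsistent descriptor names for {c.structure}"
            )
        vectors.append(np.asarray(values, dtype=float))
    if failures:
        raise BackendError(
            f"descriptor backend failed on {len(failures)} compound(s):\n" + "\n".join(failures)
        )
    assert names is not None
    X = np.vstack(vectors)

    nonfinite = ~np.isfinite(X).all(axis=0)
    if nonfinite.any():
        dropped = [n for n, bad in zip(names, nonfinite) if bad]
        logger.warning("dropping %d column(s) with non-finite values: %s", len(dropped), dropped)
    constant = np.zeros(X.shape[1], dtype=bool)
    finite_cols = ~nonfinite
    constant[finite_cols] = (
        X[:, finite_cols].max(axis=0) == X[:, finite_cols].min(axis=0)
    )
    keep = ~(nonfinite | constant)
    X = X[:, keep]
    kept_names = [n for n, k in zip(names, keep) if k]

    matrix = DescriptorMatrix(
        descriptor_names=kept_names,
        rows={c: X[i] for i, c in enumerate(compounds)},
        backend_id=backend_id,
    )
    if select is not None:
        matrix = matrix.select(select)
    return matrix


# ---------------------------------------------------------------------------
# Shipped backends


class RDKitDescriptorBackend:
    """2D physicochemical/topological descriptors from RDKit.

    Uses a fixed, documented subset of RDKit's descriptor registry (size,
    lipophilicity, polarity, connectivity, charge-surface terms). 2D only:
    no conformer generation, so results are bit-for-bit reproducible.
    """

    DESCRIPTOR_NAMES = (
        "MolWt", "MolLogP", "MolMR", "TPSA", "HeavyAtomCount",
        "NumHAcceptors", "NumHDonors", "NumRotatableBonds", "RingCount",
        "FractionCSP3", "BalabanJ", "BertzCT", "Chi0v", "Chi1v", "Chi2v",
        "Kappa1", "Kappa2", "Kappa3", "HallKierAlpha", "LabuteASA",
        "PEOE_VSA1", "PEOE_VSA2", "SMR_VSA1", "SlogP_VSA1", "EState_VSA1",
        "MaxPartialCharge", "MinPartialCharge", "NumAromaticRings",
        "NumAliphaticRings", "NumHeteroatoms",
    )

    backend_id = "rdkit-2d"

    def __call__(self, structure: str) -> tuple[Sequence[str], Sequence[float]]:
        from rdkit import Chem
        from rdkit.Chem import Descriptors

        mol = Chem.MolFromSmiles(structure)
        if mol is None:
            raise BackendError(f"unparsable structure: {structure!r}")
        fns = dict(Descriptors.descList)
        values = [float(fns[n](mol)) for n in self.DESCRIPTOR_NAMES]
        return list(self.DESCRIPTOR_NAMES), values


class DictBackend:
    """Backend over a precomputed mapping structure -> vector."""

    def __init__(self, names: Sequence[str], table: Mapping[str, Sequence[float]],
                 backend_id: str = "dict"):
        self.names = list(names)
        self.table = {k: np.asarray(v, dtype=float) for k, v in table.items()}
        self.backend_id = backend_id

    def __call__(self, structure: str) -> tuple[Sequence[str], Sequence[float]]:
        if structure not in self.table:
            raise BackendError(f"no precomputed descriptors for {structure!r}")
        return self.names, self.table[structure]


def toy_backend(structure: str) -> tuple[Sequence[str], Sequence[float]]:
    """Deterministic string-derived descriptors for tests; no chemistry."""
    s = structure
    return (
        ["length", "alpha_sum", "digit_sum", "bias"],
        [float(len(s)), float(sum(ord(c) for c in s if c.isalpha()) % 97),
         float(sum(int(c) for c in s if c.isdigit())), 1.0],
    )


def read_descriptor_cache(path: str | Path, backend_id: str = "cache") -> DescriptorMatrix:
    """Load a matrix from a cache file: first column = canonical structure."""
    df = pd.read_csv(path, float_precision="round_trip")
    struct_col = df.columns[0]
    names = [str(c) for c in df.columns[1:]]
    rows = {
        CompoundRef(str(r[struct_col])): np.asarray([r[c] for c in names], dtype=float)
        for _, r in df.iterrows()
    }
    return DescriptorMatrix(descriptor_names=names, rows=rows, backend_id=backend_id)


def write_descriptor_cache(matrix: DescriptorMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Column scaling (leakage-safe: statistics from the training rows only)


@dataclass
class ColumnScaler:
    """Fitted per-column affine scaler: scaled = (x - shift) / scale.

    Degenerate columns (zero spread on the fit set) get scale 1 and map to 0
    relative to their shift.
    """

    method: str
    shift: np.ndarray
    scale: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.shift) / self.scale

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) * self.scale + self.shift


def scale_columns(
    matrix: DescriptorMatrix,
    method: str = "zscore",
    fit_on: Iterable[CompoundRef] | None = None,
) -> tuple[DescriptorMatrix, ColumnScaler]:
    """Scale matrix columns with statistics computed on ``fit_on`` rows only.

    ``method`` is one of ``none`` (identity), ``zscore`` (mean 0, sd 1 on the
    fit set), ``minmax`` (fit-set range to [0, 1]). Fitting on a training
    subset and applying to all rows is what keeps cross-validation free of
    test-fold leakage through scaling.
    """
    fit_set = list(fit_on) if fit_on is not None else list(matrix.rows)
    if not fit_set:
        raise ConfigError("fit_on must be non-empty")
    missing = matrix.covers(fit_set)
    if missing:
        raise ConfigError(f"fit_on compounds not in matrix: {[c.structure for c in missing]}")
    F = np.vstack([matrix.rows[c] for c in fit_set])

    if method == "none":
        shift = np.zeros(matrix.n_descriptors)
        scale = np.ones(matrix.n_descriptors)
    elif method == "zscore":
        shift = F.mean(axis=0)
        sd = F.std(axis=0, ddof=0)
        scale = np.where(sd > 0, sd, 1.0)
    elif method == "minmax":
        lo, hi = F.min(axis=0), F.max(axis=0)
        shift = lo
        rng = hi - lo
        scale = np.where(rng > 0, rng, 1.0)
    else:
        raise ConfigError(f"unknown scaling method: {method!r}")

    scaler = ColumnScaler(method=method, shift=shift, scale=scale)
    scaled = DescriptorMatrix(
        descriptor_names=list(matrix.descriptor_names),
        rows={c: scaler.transform(v) for c, v in matrix.rows.items()},
        backend_id=matrix.backend_id,
    )
    return scaled, scaler
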