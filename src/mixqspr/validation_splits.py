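"""Mixture-aware external cross-validation protocols.

Random ("points out") splitting overestimates the performance of mixture
property models: the same mixture, at a slightly different composition, sits
in both the training and the external fold. Three protocols of increasing
rigor are implemented:

* ``POINTS_OUT``    — data points are placed in folds at random; the same
  mixture occurs on both sides. Weakest; kept for comparison and emits a
  warning.
* ``MIXTURES_OUT``  — all data points of one mixture (same unordered component
  pair, any composition) share a fold, so every mixture is in the training set
  or the external set but never both.
* ``COMPOUNDS_OUT`` — compounds are partitioned into groups; each mixture is
  anchored to one of its compounds and follows that compound's group, and all
  records containing a fold's anchor compounds are excluded from that fold's
  training set. Every external record therefore contains at least one compound
  (its anchor) that is absent from the training set actually used. Hardest:
  the model must extrapolate to unseen chemistry.

The compounds-out guarantee cannot in general be met by a plain partition:
a compound appearing in mixtures anchored to different groups would have to
be simultaneously absent from several training sets. Hence each plan carries
per-fold *training exclusions* (purging), and :func:`audit_plan` verifies the
guarantee against the effective training set by brute force.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .mixture_data import CompoundRef, MixtureDataset

PROTOCOLS = ("POINTS_OUT", "MIXTURES_OUT", "COMPOUNDS_OUT")


@dataclass
class AuditReport:
    """Brute-force verification of a plan's protocol guarantee."""

    protocol: str
    n_violations: int
    violating_records: list[int]
    fold_sizes: list[int]
    n_training_excluded: list[int]
    notes: str = ""

    @property
    def ok(self) -> bool:
        return self.n_violations == 0

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "n_violations": self.n_violations,
            "violating_records": list(self.violating_records),
            "fold_sizes": list(self.fold_sizes),
            "n_training_excluded": list(self.n_training_excluded),
            "notes": self.notes,
        }


@dataclass
class FoldPlan:
    """Assignment of record indices to k external folds under one protocol.

    ``training_exclusions[f]`` lists records that are neither external in fold
    f nor usable for fold f's training (compounds-out purging); empty for the
    other protocols. ``audit`` holds the verification result.
    """

    protocol: str
    k: int
    assignment: dict[int, int]
    seed: int
    training_exclusions: dict[int, list[int]] = field(default_factory=dict)
    audit: AuditReport | None = None

    def test_indices(self, fold: int) -> list[int]:
        return sorted(i for i, f in self.assignment.items() if f == fold)

    def train_indices(self, fold: int) -> list[int]:
        excluded = set(self.training_exclusions.get(fold, ()))
        return sorted(i for i, f in self.assignment.items() if f != fold and i not in excluded)

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.k
        for f in self.assignment.values():
            sizes[f] += 1
        return sizes

    def to_json(self, path: str | Path) -> None:
        payload = {
            "protocol": self.protocol,
            "k": self.k,
            "seed": self.seed,
            "assignment": {str(i): f for i, f in sorted(self.assignment.items())},
            "training_exclusions": {
                str(f): sorted(v) for f, v in sorted(self.training_exclusions.items())
            },
            "audit": self.audit.to_dict() if self.audit else None,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FoldPlan":
        payload = json.loads(Path(path).read_text())
        audit = AuditReport(**payload["audit"]) if payload.get("audit") else None
        return cls(
            protocol=payload["protocol"],
            k=int(payload["k"]),
            assignment={int(i): int(f) for i, f in payload["assignment"].items()},
            seed=int(payload["seed"]),
            training_exclusions={
                int(f): [int(i) for i in v]
                for f, v in payload.get("training_exclusions", {}).items()
            },
            audit=audit,
        )


def _check_k(n: int, k: int) -> None:
    if k < 2:
        raise ConfigError(f"k must be >= 2, got {k}")
    if k > n:
        raise ConfigError(f"k = {k} exceeds the number of assignable units ({n})")


def points_out_folds(dataset: MixtureDataset, k: int, seed: int) -> FoldPlan:
    """Random balanced assignment of individual data points to k folds.

    Fold sizes differ by at most one. The same mixture typically spans several
    folds, so metrics from this protocol estimate interpolation to new
    compositions only.
    """
    n = len(dataset.records)
    _check_k(n, k)
    warnings.warn(
        "points-out is the weakest validation protocol: the same mixture occurs in "
        "both training and external folds",
        stacklevel=2,
    )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = {int(idx): pos % k for pos, idx in enumerate(order)}
    plan = FoldPlan("POINTS_OUT", k, assignment, seed)
    plan.audit = audit_plan(plan, dataset)
    return plan


def _grouped_assignment(
    groups: list[list[int]], k: int, rng: np.random.Generator
) -> dict[int, int]:
    """Greedy largest-first bin packing of record groups into k folds.

    Balances record counts: groups are placed in decreasing size order, each
    into the currently lightest fold. Ties are broken by a seeded random
    group order, so plans are reproducible but not degenerate.
    """
    order = rng.permutation(len(groups))
    ranked = sorted(order, key=lambda gi: -len(groups[gi]))
    loads = [0] * k
    assignment: dict[int, int] = {}
    for gi in ranked:
        f = int(np.argmin(loads))
        for i in groups[gi]:
            assignment[i] = f
        loads[f] += len(groups[gi])
    return assignment


def mixtures_out_folds(dataset: MixtureDataset, k: int, seed: int) -> FoldPlan:
    """All compositions of one mixture share a fold.

    Mixtures (unordered component pairs; pure records count as their own
    one-compound group) are packed greedily largest-first to balance record
    counts across folds.
    """
    by_pair: dict[tuple[str, ...], list[int]] = {}
    for i, r in enumerate(dataset.records):
        by_pair.setdefault(r.pair_key(), []).append(i)
    if len(by_pair) < k:
        raise ConfigError(f"only {len(by_pair)} distinct mixtures for k = {k} folds")
    rng = np.random.default_rng(seed)
    assignment = _grouped_assignment(list(by_pair.values()), k, rng)
    plan = FoldPlan("MIXTURES_OUT", k, assignment, seed)
    plan.audit = audit_plan(plan, dataset)
    return plan


def compounds_out_folds(dataset: MixtureDataset, k: int, seed: int) -> FoldPlan:
    """Compounds and their mixtures leave the training set together.

    Compounds are randomly partitioned into k groups. Each mixture is anchored
    to one of its two compounds — chosen greedily to balance record counts —
    and all its records follow the anchor's group; pure records follow their
    compound's group. Records outside fold f that contain any of fold f's
    anchor compounds are excluded from fold f's training set, which enforces
    the protocol guarantee: every external record has at least one compound
    absent from the training set used against it.
    """
    compounds = dataset.compounds()
    if len(compounds) < k:
        raise ConfigError(f"only {len(compounds)} distinct compounds for k = {k} folds")
    rng = np.random.default_rng(seed)

    shuffled = list(rng.permutation(len(compounds)))
    group: dict[CompoundRef, int] = {
        compounds[ci]: pos % k for pos, ci in enumerate(shuffled)
    }

    by_pair: dict[tuple[str, ...], list[int]] = {}
    for i, r in enumerate(dataset.records):
        by_pair.setdefault(r.pair_key(), []).append(i)

    # Largest mixtures first; anchor to whichever component's fold is lighter.
    pair_order = rng.permutation(len(by_pair))
    pair_items = list(by_pair.items())
    ranked = sorted(pair_order, key=lambda pi: -len(pair_items[pi][1]))

    loads = [0] * k
    assignment: dict[int, int] = {}
    anchor_of_fold: dict[int, set[CompoundRef]] = {f: set() for f in range(k)}
    for pi in ranked:
        key, idxs = pair_items[pi]
        rec = dataset.records[idxs[0]]
        candidates = [(group[c], c) for c in rec.compounds()]
        f, anchor = min(candidates, key=lambda fc: (loads[fc[0]], fc[0]))
        for i in idxs:
            assignment[i] = f
        loads[f] += len(idxs)
        anchor_of_fold[f].add(anchor)

    # Purge: a record outside fold f containing one of f's anchors would leak
    # that anchor into f's training set.
    exclusions: dict[int, list[int]] = {f: [] for f in range(k)}
    for f in range(k):
        anchors = anchor_of_fold[f]
        for i, r in enumerate(dataset.records):
            if assignment[i] != f and any(c in anchors for c in r.compounds()):
                exclusions[f].append(i)

    plan = FoldPlan("COMPOUNDS_OUT", k, assignment, seed, training_exclusions=exclusions)
    plan.audit = audit_plan(plan, dataset)
    return plan


def audit_plan(plan: FoldPlan, dataset: MixtureDataset) -> AuditReport:
    """Brute-force verification of a plan's protocol guarantee.

    POINTS_OUT: the assignment is an exhaustive partition with fold sizes
    differing by at most one. MIXTURES_OUT: no unordered component pair spans
    two folds. COMPOUNDS_OUT: every external record contains at least one
    compound that appears in no record of the training set effectively used
    for its fold (complement minus the fold's training exclusions).
    """
    n = len(dataset.records)
    if set(plan.assignment) != set(range(n)):
        raise ConfigError("plan does not cover the dataset's records exactly")

    fold_sizes = plan.fold_sizes()
    n_excluded = [len(plan.training_exclusions.get(f, ())) for f in range(plan.k)]
    violating: list[int] = []
    notes = ""

    if plan.protocol == "POINTS_OUT":
        if max(fold_sizes) - min(fold_sizes) > 1:
            notes = "fold sizes differ by more than one"
            violating = []
    elif plan.protocol == "MIXTURES_OUT":
        pair_folds: dict[tuple[str, ...], set[int]] = {}
        for i, r in enumerate(dataset.records):
            pair_folds.setdefault(r.pair_key(), set()).add(plan.assignment[i])
        straddlers = {p for p, fs in pair_folds.items() if len(fs) > 1}
        violating = [
            i for i, r in enumerate(dataset.records) if r.pair_key() in straddlers
        ]
        if straddlers:
            notes = f"{len(straddlers)} mixture(s) span more than one fold"
    elif plan.protocol == "COMPOUNDS_OUT":
        for f in range(plan.k):
            train = plan.train_indices(f)
            train_compounds = {
                c for i in train for c in dataset.records[i].compounds()
            }
            for i in plan.test_indices(f):
                r = dataset.records[i]
                if all(c in train_compounds for c in r.compounds()):
                    violating.append(i)
        if violating:
            notes = "records without a novel compound relative to their training set"
    else:
        raise ConfigError(f"unknown protocol: {plan.protocol!r}")

    return AuditReport(
        protocol=plan.protocol,
        n_violations=len(violating),
        violating_records=sorted(violating),
        fold_sizes=fold_sizes,
        n_training_excluded=n_excluded,
        notes=notes,
    )


def make_plan(dataset: MixtureDataset, protocol: str, k: int, seed: int) -> FoldPlan:
    """Dispatch on protocol name (case-insensitive)."""
    p = protocol.upper()
    if p == "POINTS_OUT":
        return points_out_folds(dataset, k, seed)
    if p == "MIXTURES_OUT":
        return mixtures_out_folds(dataset, k, seed)
    if p == "COMPOUNDS_OUT":
        return compounds_out_folds(dataset, k, seed)
    raise ConfigError(f"unknown protocol: {protocol!r}")
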