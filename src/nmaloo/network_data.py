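"""Data model, I/O and geometry validation for binary-outcome NMA datasets.

A network is stored in long ("arm-level") form: one record per trial arm
carrying the study id, treatment label, event count ``y_ik`` and sample size
``n_ik``.  The set of treatments compared in trial *i* is written ``S_i``.
The canonical interchange format is a UTF-8 CSV with header
``study,treatment,events,n``; an optional YAML sidecar carries the outcome
direction, reference treatment and an explicit treatment order.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import yaml

logger = logging.getLogger("nmaloo")

OUTCOME_DIRECTIONS = ("beneficial", "harmful")

#: fraction of zero-event arms above which a rare-event warning is issued
ZERO_ARM_WARN_FRACTION = 0.25


class NetworkValidationError(ValueError):
    """A network violates a structural invariant (named study in message)."""


@dataclass(frozen=True, order=True)
class ArmRecord:
    """One trial arm: ``y_ik`` events out of ``n_ik`` subjects."""

    study_id: str
    treatment_id: str
    events: int
    sample_size: int

    def __post_init__(self) -> None:
        if self.sample_size < 1:
            raise NetworkValidationError(
                f"study {self.study_id!r}, treatment {self.treatment_id!r}: "
                f"sample_size must be >= 1, got {self.sample_size}"
            )
        if not 0 <= self.events <= self.sample_size:
            raise NetworkValidationError(
                f"study {self.study_id!r}, treatment {self.treatment_id!r}: "
                f"events must satisfy 0 <= y <= n, got y={self.events}, "
                f"n={self.sample_size}"
            )


@dataclass(frozen=True)
class NMANetwork:
    """An NMA dataset: K treatments, I trials, arm-level binary outcomes.

    ``treatments`` fixes the treatment order (indices 1..K in first-appearance
    order unless overridden); all model code works on indices, labels appear
    only at I/O boundaries.
    """

    treatments: tuple[str, ...]
    arms: tuple[ArmRecord, ...]
    outcome_direction: str = "beneficial"
    name: str = "network"

    def __post_init__(self) -> None:
        if self.outcome_direction not in OUTCOME_DIRECTIONS:
            raise NetworkValidationError(
                f"outcome_direction must be one of {OUTCOME_DIRECTIONS}, "
                f"got {self.outcome_direction!r}"
            )
        seen_pairs: set[tuple[str, str]] = set()
        per_study: dict[str, list[str]] = {}
        tset = set(self.treatments)
        if len(tset) != len(self.treatments):
            raise NetworkValidationError("duplicate treatment labels")
        for arm in self.arms:
            key = (arm.study_id, arm.treatment_id)
            if key in seen_pairs:
                raise NetworkValidationError(
                    f"study {arm.study_id!r}: duplicate arm for treatment "
                    f"{arm.treatment_id!r}"
                )
            seen_pairs.add(key)
            if arm.treatment_id not in tset:
                raise NetworkValidationError(
                    f"study {arm.study_id!r}: treatment {arm.treatment_id!r} "
                    "not in the treatments list"
                )
            per_study.setdefault(arm.study_id, []).append(arm.treatment_id)
        for sid, trts in per_study.items():
            if len(trts) < 2:
                raise NetworkValidationError(
                    f"study {sid!r} has a single arm; every trial must "
                    "compare at least two distinct treatments"
                )
        n_zero = sum(1 for a in self.arms if a.events == 0)
        if self.arms and n_zero / len(self.arms) > ZERO_ARM_WARN_FRACTION:
            logger.warning(
                "network %r: %d of %d arms have zero events; rare-event "
                "networks can bias binomial NMA estimates",
                self.name, n_zero, len(self.arms),
            )

    # -- convenience views -------------------------------------------------
    @property
    def n_treatments(self) -> int:
        return len(self.treatments)

    @property
    def study_ids(self) -> tuple[str, ...]:
        """Distinct study ids in first-appearance order."""
        out: list[str] = []
        seen: set[str] = set()
        for arm in self.arms:
            if arm.study_id not in seen:
                seen.add(arm.study_id)
                out.append(arm.study_id)
        return tuple(out)

    @property
    def n_trials(self) -> int:
        return len(self.study_ids)

    def treatment_index(self, label: str) -> int:
        """0-based index of a treatment label."""
        try:
            return self.treatments.index(label)
        except ValueError:
            raise KeyError(f"unknown treatment {label!r}") from None

    def study_treatments(self, study_id: str) -> tuple[str, ...]:
        """The treatment set S_i of one trial (in arm order)."""
        trts = tuple(a.treatment_id for a in self.arms if a.study_id == study_id)
        if not trts:
            raise KeyError(f"unknown study {study_id!r}")
        return trts

    def arms_of(self, study_id: str) -> tuple[ArmRecord, ...]:
        return tuple(a for a in self.arms if a.study_id == study_id)


@dataclass(frozen=True)
class GeometrySummary:
    """Table-1-style geometry: trial/treatment counts, per-treatment
    frequencies (number of trials containing the treatment), connectivity of
    the co-occurrence graph, and the number of zero-event arms."""

    n_trials: int
    n_treatments: int
    treatment_frequency: Mapping[str, int]
    min_frequency: int
    max_frequency: int
    connected: bool
    n_zero_event_arms: int


@dataclass(frozen=True)
class InclusionReport:
    """Report of the inclusion rule: every treatment compared in at least
    ``min_frequency`` trials, and the network connected."""

    passed: bool
    low_frequency_treatments: tuple[str, ...]
    connected: bool
    min_frequency: int


def comparison_graph(net: NMANetwork) -> nx.Graph:
    """Treatments as nodes, co-occurrence in any trial as edges."""
    g = nx.Graph()
    g.add_nodes_from(net.treatments)
    for sid in net.study_ids:
        trts = net.study_treatments(sid)
        for i, a in enumerate(trts):
            for b in trts[i + 1:]:
                g.add_edge(a, b)
    return g


def geometry_summary(net: NMANetwork) -> GeometrySummary:
    freq = {t: 0 for t in net.treatments}
    for sid in net.study_ids:
        for t in set(net.study_treatments(sid)):
            freq[t] += 1
    values = list(freq.values()) or [0]
    return GeometrySummary(
        n_trials=net.n_trials,
        n_treatments=net.n_treatments,
        treatment_frequency=freq,
        min_frequency=min(values),
        max_frequency=max(values),
        connected=nx.is_connected(comparison_graph(net)) if net.treatments else True,
        n_zero_event_arms=sum(1 for a in net.arms if a.events == 0),
    )


def validate_inclusion(net: NMANetwork, min_frequency: int = 2) -> InclusionReport:
    """Check the inclusion rule that each treatment is compared in at least
    ``min_frequency`` trials (default 2) and the network is connected.

    Report-only: never raises on failure.
    """
    summ = geometry_summary(net)
    low = tuple(
        t for t in net.treatments if summ.treatment_frequency[t] < min_frequency
    )
    return InclusionReport(
        passed=(not low) and summ.connected,
        low_frequency_treatments=low,
        connected=summ.connected,
        min_frequency=min_frequency,
    )


def remove_trial(net: NMANetwork, study_id: str) -> NMANetwork:
    """Return a new network without the given study.

    Treatments that no longer appear in any arm are pruned from the
    treatments list; the input network is never modified.
    """
    if study_id not in net.study_ids:
        raise KeyError(f"unknown study {study_id!r}")
    kept = tuple(a for a in net.arms if a.study_id != study_id)
    present = {a.treatment_id for a in kept}
    treatments = tuple(t for t in net.treatments if t in present)
    return NMANetwork(
        treatments=treatments,
        arms=kept,
        outcome_direction=net.outcome_direction,
        name=net.name,
    )


# -- I/O -------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def read_network(
    path: str | Path,
    outcome_direction: str | None = None,
    name: str | None = None,
) -> NMANetwork:
    """Read a network from a long CSV (``study,treatment,events,n``).

    A YAML sidecar next to the CSV (same stem, ``.yaml``) may declare
    ``outcome_direction``, ``name`` and an explicit ``treatments`` order;
    explicit arguments win over the sidecar.  Treatment order defaults to
    first appearance.
    """
    path = Path(path)
    sidecar: dict = {}
    sc = _sidecar_path(path)
    if sc.exists():
        sidecar = yaml.safe_load(sc.read_text()) or {}
    direction = outcome_direction or sidecar.get("outcome_direction", "beneficial")
    net_name = name or sidecar.get("name", path.stem)

    arms: list[ArmRecord] = []
    order: list[str] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"study", "treatment", "events", "n"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise NetworkValidationError(
                f"{path}: header must contain columns {sorted(required)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                events = int(row["events"])
                n = int(row["n"])
            except (TypeError, ValueError) as exc:
                raise NetworkValidationError(
                    f"{path}:{lineno}: non-integer events/n in row {row!r}"
                ) from exc
            arm = ArmRecord(str(row["study"]).strip(), str(row["treatment"]).strip(), events, n)
            arms.append(arm)
            if arm.treatment_id not in order:
                order.append(arm.treatment_id)

    declared = sidecar.get("treatments")
    if declared:
        declared = [str(t) for t in declared]
        if set(declared) != set(order):
            raise NetworkValidationError(
                f"{path}: sidecar treatment order {declared} does not match "
                f"treatments present in the data {order}"
            )
        order = declared
    return NMANetwork(tuple(order), tuple(arms), direction, net_name)


def write_network(net: NMANetwork, path: str | Path, sidecar: bool = True) -> None:
    """Write the long CSV (and a YAML sidecar with direction and order)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["study", "treatment", "events", "n"])
        for a in net.arms:
            writer.writerow([a.study_id, a.treatment_id, a.events, a.sample_size])
    if sidecar:
        _sidecar_path(path).write_text(
            yaml.safe_dump(
                {
                    "name": net.name,
                    "outcome_direction": net.outcome_direction,
                    "treatments": list(net.treatments),
                },
                sort_keys=False,
            )
        )
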