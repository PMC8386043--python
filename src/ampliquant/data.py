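"""Core data containers shared by the I/O, analysis and simulation modules.

A :class:`RunData` holds one qPCR run: reactions with raw amplification
(``adp``: cycle, fluorescence) and melting (``mdp``: temperature,
fluorescence) data points, plus sample and target annotation.  Raw series are
plain Python lists of tuples so that file round-trips are field-exact; the
analysis modules convert them to numpy arrays on entry and never mutate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

SAMPLE_TYPES = ("unknown", "positive_control", "negative_control")


@dataclass
class SampleInfo:
    """A sample and its role in the run (unknown or control)."""

    sample_id: str
    sample_type: str = "unknown"

    def validate(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValidationError(
                f"sample {self.sample_id!r}: sample_type {self.sample_type!r} "
                f"not one of {SAMPLE_TYPES}"
            )


@dataclass
class TargetInfo:
    """An assay target: identifier, expected product Tm and dye class.

    ``expected_tm`` is the previously validated melting temperature of the
    intended amplicon in degC; ``dye_saturating`` records whether the run used a
    saturating DNA-binding dye, which is required for melt-based correction of
    the reported quantities.
    """

    target_id: str
    expected_tm: float | None = None
    dye_saturating: bool = False

    def validate(self) -> None:
        if self.expected_tm is not None and not (40.0 <= self.expected_tm <= 99.0):
            raise ValidationError(
                f"target {self.target_id!r}: expected_tm {self.expected_tm} "
                "outside [40, 99] degC"
            )


@dataclass
class ReactionRecord:
    """One well: raw amplification and/or melting data plus annotation."""

    well: str
    sample_id: str
    target_id: str
    adp: list[tuple[int, float]] = field(default_factory=list)
    mdp: list[tuple[float, float]] = field(default_factory=list)

    @property
    def cycles(self) -> np.ndarray:
        return np.array([c for c, _ in self.adp], dtype=int)

    @property
    def fluorescence(self) -> np.ndarray:
        return np.array([f for _, f in self.adp], dtype=float)

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([t for t, _ in self.mdp], dtype=float)

    @property
    def melt_fluorescence(self) -> np.ndarray:
        return np.array([f for _, f in self.mdp], dtype=float)

    def validate(self) -> None:
        if not self.adp and not self.mdp:
            raise ValidationError(f"well {self.well!r}: no adp or mdp data")
        if self.adp:
            cyc = [c for c, _ in self.adp]
            if any(b - a != 1 for a, b in zip(cyc, cyc[1:])) or (cyc and cyc[0] < 1):
                raise ValidationError(
                    f"well {self.well!r}: adp cycles must be consecutive "
                    "integers starting at >= 1"
                )
        if self.mdp:
            tmp = [t for t, _ in self.mdp]
            if any(b <= a for a, b in zip(tmp, tmp[1:])):
                raise ValidationError(
                    f"well {self.well!r}: mdp temperatures must be strictly increasing"
                )


@dataclass
class RunData:
    """A whole plate: reactions plus the sample and target dictionaries."""

    run_id: str
    reactions: list[ReactionRecord] = field(default_factory=list)
    targets: dict[str, TargetInfo] = field(default_factory=dict)
    samples: dict[str, SampleInfo] = field(default_factory=dict)

    def validate(self) -> None:
        for s in self.samples.values():
            s.validate()
        for t in self.targets.values():
            t.validate()
        wells = [r.well for r in self.reactions]
        if len(wells) != len(set(wells)):
            dupes = sorted({w for w in wells if wells.count(w) > 1})
            raise ValidationError(f"duplicate well identifiers: {dupes}")
        for r in self.reactions:
            r.validate()
            if r.sample_id not in self.samples:
                raise ValidationError(
                    f"well {r.well!r}: unknown sample_id {r.sample_id!r}"
                )
            if r.target_id not in self.targets:
                raise ValidationError(
                    f"well {r.well!r}: unknown target_id {r.target_id!r}"
                )

    def reaction(self, well: str) -> ReactionRecord:
        for r in self.reactions:
            if r.well == well:
                return r
        raise KeyError(well)

    def sample_type(self, well: str) -> str:
        return self.samples[self.reaction(well).sample_id].sample_type


@dataclass
class AmplificationCurve:
    """One reaction's raw amplification series as numpy arrays."""

    well: str
    sample_id: str
    target_id: str
    cycles: np.ndarray
    fluorescence: np.ndarray

    @classmethod
    def from_record(cls, rec: ReactionRecord) -> "AmplificationCurve":
        return cls(rec.well, rec.sample_id, rec.target_id,
                   rec.cycles, rec.fluorescence)


@dataclass
class MeltCurve:
    """One reaction's raw melting series as numpy arrays."""

    well: str
    sample_id: str
    target_id: str
    temperatures: np.ndarray
    fluorescence: np.ndarray

    @classmethod
    def from_record(cls, rec: ReactionRecord) -> "MeltCurve":
        return cls(rec.well, rec.sample_id, rec.target_id,
                   rec.temperatures, rec.melt_fluorescence)
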