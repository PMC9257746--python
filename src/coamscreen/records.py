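"""Domain records for coamorphous (COAM) screening.

A screen pairs one active pharmaceutical ingredient (API) with a coformer
and asks whether the 1:1 mixture forms a single-phase amorphous system.
Each component carries the physicochemical descriptors the prediction
model consumes: molecular weight, hydrogen-bond donor/acceptor counts,
the hydrogen-bonding Hansen parameter δh and the pseudo-chemical
potential μ of the pure solute.  Each pair carries the excess enthalpies
of mixing (ΔH_mix) and of hydrogen bonding (ΔH_hb) of the two-component
system, plus the experimental outcome when known.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

from .errors import ValidationError


class Role(enum.Enum):
    """Which side of the pair a component sits on."""

    API = "API"
    COFORMER = "coformer"


class OutcomeLabel(enum.Enum):
    """Experimental or predicted classification of a pair.

    ``DECOMPOSED`` marks systems that broke down on melting during the
    hot-stage screen; they are representable but are mapped to
    ``NOT_COAM`` (or excluded) when agreement statistics are computed.
    """

    COAM = "COAM"
    NOT_COAM = "NOT_COAM"
    DECOMPOSED = "DECOMPOSED"
    UNKNOWN = "UNKNOWN"


#: Bijection between single-letter table codes and outcome labels.
LABEL_CODES = {
    "Y": OutcomeLabel.COAM,
    "N": OutcomeLabel.NOT_COAM,
    "D": OutcomeLabel.DECOMPOSED,
}
LABEL_TO_CODE = {v: k for k, v in LABEL_CODES.items()}


@dataclass(frozen=True)
class ComponentRecord:
    """One molecule (API or coformer) with its model descriptors.

    Parameters
    ----------
    name : unique text identifier (case-sensitive).
    role : Role.API or Role.COFORMER.
    mw : molecular weight, g/mol (> 0).
    hbd, hba : hydrogen-bond donor / acceptor counts (>= 0).
    delta_h_hansen : Hansen hydrogen-bonding parameter δh, MPa^0.5;
        ``None`` when not available.
    mu : pseudo-chemical potential of the pure solute, kcal/mol;
        ``None`` when not available.
    structure : optional SMILES text.
    """

    name: str
    role: Role
    mw: float
    hbd: int
    hba: int
    delta_h_hansen: Optional[float] = None
    mu: Optional[float] = None
    structure: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("component name must be non-empty")
        if not (self.mw > 0 and math.isfinite(self.mw)):
            raise ValidationError(f"{self.name}: mw must be a positive finite number, got {self.mw}")
        if self.hbd < 0 or self.hba < 0:
            raise ValidationError(f"{self.name}: hbd/hba counts must be non-negative")
        if self.delta_h_hansen is not None and not (
            self.delta_h_hansen >= 0 and math.isfinite(self.delta_h_hansen)
        ):
            raise ValidationError(f"{self.name}: delta_h_hansen must be finite and >= 0")
        if self.mu is not None and not math.isfinite(self.mu):
            raise ValidationError(f"{self.name}: mu must be finite")


@dataclass(frozen=True)
class PairRecord:
    """An API-coformer combination.

    ``dh_mix`` and ``dh_hb`` (kcal/mol) are the excess enthalpies of the
    two-component system; they may be absent on label-only fixtures but
    must be finite whenever present, and are required for feature
    assembly.  ``predicted_label`` / ``coam_value`` hold externally
    supplied predictions (e.g. printed screening tables) when available.
    """

    api: ComponentRecord
    coformer: ComponentRecord
    dh_mix: Optional[float] = None
    dh_hb: Optional[float] = None
    experimental_label: OutcomeLabel = OutcomeLabel.UNKNOWN
    label_short: Optional[str] = None
    predicted_label: Optional[OutcomeLabel] = None
    coam_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.api.role is not Role.API:
            raise ValidationError(f"pair {self.key}: '{self.api.name}' does not have role API")
        if self.coformer.role is not Role.COFORMER:
            raise ValidationError(
                f"pair {self.key}: '{self.coformer.name}' does not have role coformer"
            )
        for fname, v in (("dh_mix", self.dh_mix), ("dh_hb", self.dh_hb)):
            if v is not None and not math.isfinite(v):
                raise ValidationError(f"pair {self.key}: {fname} must be finite, got {v}")

    @property
    def key(self) -> str:
        return f"{self.api.name}+{self.coformer.name}"

    @property
    def display_label(self) -> str:
        return self.label_short or self.key


@dataclass
class ScreenTable:
    """An ordered collection of pairs plus their component definitions.

    ``provenance`` is free-form metadata (source, seed, generator
    configuration, counting conventions) carried through I/O round trips.
    """

    pairs: list[PairRecord]
    components: dict[str, ComponentRecord] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.components:
            self.components = {}
            for p in self.pairs:
                self.components.setdefault(p.api.name, p.api)
                self.components.setdefault(p.coformer.name, p.coformer)
        for p in self.pairs:
            for comp in (p.api, p.coformer):
                known = self.components.get(comp.name)
                if known is None:
                    raise ValidationError(
                        f"pair {p.key}: component '{comp.name}' not in component table"
                    )

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def experimental_labels(self) -> list[OutcomeLabel]:
        return [p.experimental_label for p in self.pairs]
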