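"""Feature assembly for the COAM prediction model.

The model consumes one vector per API-coformer pair:

==================  =============================================  =========
feature             definition                                     units
==================  =============================================  =========
avg_mw              mean of the two molecular weights              g/mol
sum_hbd_minus_hba   (HBD-HBA)_API + (HBD-HBA)_coformer             counts
dh_mix              excess enthalpy of mixing of the pair          kcal/mol
dh_hb               excess enthalpy of hydrogen bonding            kcal/mol
d_delta_h           δh(API) - δh(coformer)                         MPa^0.5
d_mu                μ(API) - μ(coformer)                           kcal/mol
==================  =============================================  =========

The ordering above is fixed; trained models are ordering-sensitive and
record their feature set in metadata.  Differences use the
API-minus-coformer sign convention throughout.  A five-feature variant
drops ``d_mu``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import DescriptorError, DomainError, TableParseError
from .records import ComponentRecord, PairRecord, ScreenTable

#: Canonical six-feature ordering (the model is ordering-sensitive).
FEATURE_ORDER = ("avg_mw", "sum_hbd_minus_hba", "dh_mix", "dh_hb", "d_delta_h", "d_mu")
#: Five-feature variant without the pseudo-chemical-potential difference.
FEATURE_ORDER_NO_MU = FEATURE_ORDER[:-1]

FEATURE_SETS = {
    "six_feature": FEATURE_ORDER,
    "five_feature_no_mu": FEATURE_ORDER_NO_MU,
}


@dataclass(frozen=True)
class FeatureVector:
    """PLS-DA input variables for one pair; see module docstring for units."""

    avg_mw: float
    sum_hbd_minus_hba: float
    dh_mix: float
    dh_hb: float
    d_delta_h: float
    d_mu: Optional[float] = None

    def as_array(self, feature_set: str = "six_feature") -> np.ndarray:
        names = FEATURE_SETS[feature_set]
        values = []
        for n in names:
            v = getattr(self, n)
            if v is None:
                raise DescriptorError(f"feature '{n}' absent but required by '{feature_set}'")
            values.append(float(v))
        return np.array(values)


def average_molecular_weight(mw_api: float, mw_coformer: float) -> float:
    """Arithmetic mean of the two components' molecular weights (g/mol)."""
    if not (mw_api > 0 and mw_coformer > 0):
        raise DomainError("molecular weights must be positive")
    return (mw_api + mw_coformer) / 2.0


def donor_acceptor_difference_sum(
    hbd_api: int, hba_api: int, hbd_coformer: int, hba_coformer: int
) -> int:
    """Sum over both components of (donor count - acceptor count)."""
    if min(hbd_api, hba_api, hbd_coformer, hba_coformer) < 0:
        raise DomainError("donor/acceptor counts must be non-negative")
    return (hbd_api - hba_api) + (hbd_coformer - hba_coformer)


def pair_difference(value_api: float, value_coformer: float) -> float:
    """API-minus-coformer difference of a per-component property."""
    if not (math.isfinite(value_api) and math.isfinite(value_coformer)):
        raise DomainError("pair_difference requires finite inputs")
    return value_api - value_coformer


def _require(value, field: str, component: str):
    if value is None:
        raise DescriptorError(f"component '{component}' is missing required field '{field}'")
    return value


def assemble_feature_vector(
    api: ComponentRecord, coformer: ComponentRecord, pair: PairRecord,
    feature_set: str = "six_feature",
) -> FeatureVector:
    """Assemble the feature vector for one pair.

    Raises :class:`DescriptorError` naming the field and component when a
    required descriptor is absent.  Under the five-feature set μ is not
    required and ``d_mu`` is carried only when both components have μ.
    """
    if pair.dh_mix is None:
        raise DescriptorError(f"pair '{pair.key}' is missing required field 'dh_mix'")
    if pair.dh_hb is None:
        raise DescriptorError(f"pair '{pair.key}' is missing required field 'dh_hb'")
    d_mu: Optional[float]
    if api.mu is None or coformer.mu is None:
        if feature_set == "six_feature":
            missing = api if api.mu is None else coformer
            raise DescriptorError(f"component '{missing.name}' is missing required field 'mu'")
        d_mu = None
    else:
        d_mu = pair_difference(api.mu, coformer.mu)
    return FeatureVector(
        avg_mw=average_molecular_weight(api.mw, coformer.mw),
        sum_hbd_minus_hba=donor_acceptor_difference_sum(api.hbd, api.hba, coformer.hbd, coformer.hba),
        dh_mix=pair.dh_mix,
        dh_hb=pair.dh_hb,
        d_delta_h=pair_difference(
            _require(api.delta_h_hansen, "delta_h_hansen", api.name),
            _require(coformer.delta_h_hansen, "delta_h_hansen", coformer.name),
        ),
        d_mu=d_mu,
    )


def feature_matrix(screen: ScreenTable, feature_set: str = "six_feature") -> pd.DataFrame:
    """Feature matrix for a whole screen: one row per pair, fixed column order.

    The index holds the pair display labels (order preserved).
    """
    names = FEATURE_SETS[feature_set]
    rows, index = [], []
    for p in screen.pairs:
        fv = assemble_feature_vector(p.api, p.coformer, p, feature_set)
        rows.append(fv.as_array(feature_set))
        index.append(p.display_label)
    return pd.DataFrame(np.array(rows).reshape(len(rows), len(names)), columns=list(names), index=index)


# --- Hansen δh group-contribution surrogate -------------------------------

_GROUP_TABLE: Optional[dict[str, float]] = None


def hansen_group_table() -> dict[str, float]:
    """Packaged Hoftyzer-Van Krevelen hydrogen-bond energy table (J/mol)."""
    global _GROUP_TABLE
    if _GROUP_TABLE is None:
        table = {}
        with resources.files("coamscreen.data").joinpath("hansen_groups.csv").open(
            encoding="utf-8"
        ) as fh:
            for row in csv.DictReader(fh):
                try:
                    table[row["group"]] = float(row["e_h_j_per_mol"])
                except (KeyError, ValueError) as exc:
                    raise TableParseError(f"hansen_groups.csv: bad row {row}") from exc
        _GROUP_TABLE = table
    return _GROUP_TABLE


def estimate_hansen_dh(group_counts: Mapping[str, int], molar_volume: float) -> float:
    """Group-contribution estimate of the Hansen δh (MPa^0.5).

    Uses the Hoftyzer-Van Krevelen form ``δh = sqrt(Σ n_i E_hi / V)``
    with the packaged per-group hydrogen-bond energies ``E_hi`` (J/mol)
    and the molar volume ``V`` in cm³/mol, so the result is in MPa^0.5.
    This is an open surrogate for solver-computed δh values; predictions
    built on it should be flagged as surrogate-based in provenance.
    """
    if not molar_volume > 0:
        raise DomainError(f"molar volume must be positive, got {molar_volume}")
    table = hansen_group_table()
    total = 0.0
    for group, count in group_counts.items():
        if group not in table:
            raise TableParseError(
                f"unknown functional group '{group}'; known groups: {sorted(table)}"
            )
        if count < 0:
            raise DomainError(f"group count for '{group}' must be non-negative")
        total += count * table[group]
    return math.sqrt(total / molar_volume)
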