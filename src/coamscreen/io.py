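"""CSV and structure I/O for screening tables.

CSV is the canonical exchange format: comma delimiter, ``.`` decimal,
UTF-8, mandatory header row.  Schemas::

    component CSV: name,role,mw,hbd,hba,delta_h_hansen,mu,smiles
                   (last four columns optional)
    pair CSV:      api,coformer,dh_mix,dh_hb,experimental_label,label_short
                   (+ optional predicted_label, coam_value)

Experimental/predicted labels use the one-letter codes Y (COAM),
N (not COAM), D (decomposed on melting); an empty cell means unknown.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .errors import (
    ContractError,
    SchemaError,
    StructureError,
    TableParseError,
    ValidationError,
)
from .records import (
    LABEL_CODES,
    LABEL_TO_CODE,
    ComponentRecord,
    OutcomeLabel,
    PairRecord,
    Role,
    ScreenTable,
)

PathLike = Union[str, Path]

_COMPONENT_REQUIRED = ("name", "role", "mw", "hbd", "hba")
_COMPONENT_OPTIONAL = ("delta_h_hansen", "mu", "smiles")
_PAIR_REQUIRED = ("api", "coformer")
_PAIR_OPTIONAL = (
    "dh_mix",
    "dh_hb",
    "experimental_label",
    "label_short",
    "predicted_label",
    "coam_value",
)


def _open_reader(path: PathLike, delimiter: str) -> tuple[list[dict], list[str]]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: file has no header row")
        header = [h.strip().lower() for h in reader.fieldnames]
        rows = []
        for row in reader:
            rows.append({h.strip().lower(): (v or "").strip() for h, v in row.items() if h})
    return rows, header


def _require_columns(header: Sequence[str], required: Sequence[str], path: PathLike) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")


def _parse_float(cell: str, column: str, row_no: int) -> float:
    try:
        return float(cell)
    except ValueError:
        raise TableParseError(
            f"row {row_no}: cannot parse '{cell}' in column '{column}' as a number"
        ) from None


def _parse_int(cell: str, column: str, row_no: int) -> int:
    try:
        return int(cell)
    except ValueError:
        raise TableParseError(
            f"row {row_no}: cannot parse '{cell}' in column '{column}' as an integer"
        ) from None


def _parse_label(cell: str, row_no: int) -> OutcomeLabel:
    if cell == "":
        return OutcomeLabel.UNKNOWN
    try:
        return LABEL_CODES[cell.upper()]
    except KeyError:
        raise TableParseError(
            f"row {row_no}: unknown label token '{cell}' (expected Y, N or D)"
        ) from None


def read_component_table(path: PathLike, delimiter: str = ",") -> list[ComponentRecord]:
    """Read a component CSV into a list of :class:`ComponentRecord`.

    Missing optional fields (δh, μ, SMILES) are recorded as absent,
    never as zero.  Raises :class:`SchemaError` for missing columns,
    :class:`TableParseError` for unparseable cells (naming the data row),
    :class:`ValidationError` for duplicate names.
    """
    rows, header = _open_reader(path, delimiter)
    _require_columns(header, _COMPONENT_REQUIRED, path)
    records: list[ComponentRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(rows, start=1):
        name = row.get("name", "")
        if not name:
            raise TableParseError(f"row {i}: empty component name")
        if name in seen:
            raise ValidationError(f"duplicate component name '{name}' (row {i})")
        seen.add(name)
        role_text = row.get("role", "").lower()
        if role_text == "api":
            role = Role.API
        elif role_text == "coformer":
            role = Role.COFORMER
        else:
            raise TableParseError(f"row {i}: unknown role '{row.get('role')}'")
        rec = ComponentRecord(
            name=name,
            role=role,
            mw=_parse_float(row["mw"], "mw", i),
            hbd=_parse_int(row["hbd"], "hbd", i),
            hba=_parse_int(row["hba"], "hba", i),
            delta_h_hansen=(
                _parse_float(row["delta_h_hansen"], "delta_h_hansen", i)
                if row.get("delta_h_hansen")
                else None
            ),
            mu=_parse_float(row["mu"], "mu", i) if row.get("mu") else None,
            structure=row.get("smiles") or None,
        )
        records.append(rec)
    return records


def read_pair_table(
    path: PathLike,
    components: Iterable[ComponentRecord],
    delimiter: str = ",",
    provenance: Optional[Mapping] = None,
) -> ScreenTable:
    """Read a pair CSV, resolving component references, into a ScreenTable.

    Label text D maps to DECOMPOSED, Y to COAM, N to NOT_COAM; a pair
    referencing an unlisted component raises :class:`ValidationError`.
    """
    comp_map = {c.name: c for c in components}
    rows, header = _open_reader(path, delimiter)
    _require_columns(header, _PAIR_REQUIRED, path)
    pairs: list[PairRecord] = []
    for i, row in enumerate(rows, start=1):
        api_name, cof_name = row.get("api", ""), row.get("coformer", "")
        for nm in (api_name, cof_name):
            if nm not in comp_map:
                raise ValidationError(
                    f"pair '{api_name}+{cof_name}' (row {i}) references unknown component '{nm}'"
                )
        coam_cell = row.get("coam_value", "")
        pairs.append(
            PairRecord(
                api=comp_map[api_name],
                coformer=comp_map[cof_name],
                dh_mix=_parse_float(row["dh_mix"], "dh_mix", i) if row.get("dh_mix") else None,
                dh_hb=_parse_float(row["dh_hb"], "dh_hb", i) if row.get("dh_hb") else None,
                experimental_label=_parse_label(row.get("experimental_label", ""), i),
                label_short=row.get("label_short") or None,
                predicted_label=(
                    _parse_label(row["predicted_label"], i) if row.get("predicted_label") else None
                ),
                coam_value=_parse_float(coam_cell, "coam_value", i) if coam_cell else None,
            )
        )
    return ScreenTable(pairs=pairs, components=comp_map, provenance=dict(provenance or {}))


def write_component_table(components: Iterable[ComponentRecord], path: PathLike) -> None:
    """Write components to CSV in the canonical schema."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(list(_COMPONENT_REQUIRED) + list(_COMPONENT_OPTIONAL))
        for c in components:
            w.writerow(
                [
                    c.name,
                    "API" if c.role is Role.API else "coformer",
                    repr(float(c.mw)),
                    c.hbd,
                    c.hba,
                    "" if c.delta_h_hansen is None else repr(float(c.delta_h_hansen)),
                    "" if c.mu is None else repr(float(c.mu)),
                    c.structure or "",
                ]
            )


def write_pair_table(table: ScreenTable, path: PathLike) -> None:
    """Write a screen's pairs to CSV in the canonical schema."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(list(_PAIR_REQUIRED) + list(_PAIR_OPTIONAL))
        for p in table.pairs:
            w.writerow(
                [
                    p.api.name,
                    p.coformer.name,
                    "" if p.dh_mix is None else repr(float(p.dh_mix)),
                    "" if p.dh_hb is None else repr(float(p.dh_hb)),
                    _label_code(p.experimental_label),
                    p.label_short or "",
                    _label_code(p.predicted_label) if p.predicted_label else "",
                    "" if p.coam_value is None else repr(float(p.coam_value)),
                ]
            )


def _label_code(label: OutcomeLabel) -> str:
    return "" if label is OutcomeLabel.UNKNOWN else LABEL_TO_CODE[label]


def derive_component_from_structure(
    smiles: str, name: str, role: Role
) -> ComponentRecord:
    """Build a ComponentRecord from a SMILES string.

    Molecular weight is summed from standard atomic weights; hydrogen
    bond donors are N-H/O-H hydrogens and acceptors are N and O atoms
    (the Lipinski convention).  δh and μ are left absent — they require
    either measured values or the group-contribution surrogate in
    :mod:`coamscreen.descriptors`.
    """
    from rdkit import Chem
    from rdkit.Chem import Descriptors, Lipinski

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"{name}: could not parse SMILES '{smiles}'")
    return ComponentRecord(
        name=name,
        role=role,
        mw=Descriptors.MolWt(mol),
        hbd=Lipinski.NHOHCount(mol),
        hba=Lipinski.NOCount(mol),
        structure=Chem.MolToSmiles(mol),
    )


def derive_components_from_sdf(path: PathLike, role: Role) -> list[ComponentRecord]:
    """Read an SDF file and derive one component per molecule (by title)."""
    from rdkit import Chem

    records = []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            raise StructureError(f"{path}: molecule {i} could not be parsed")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
        records.append(derive_component_from_structure(Chem.MolToSmiles(mol), name, role))
    return records


def write_predictions(table: ScreenTable, predictions: Sequence, path: PathLike) -> None:
    """Write per-pair prediction results next to experimental labels.

    Columns: pair label, COAM value (4 decimals), predicted class (Y/N),
    LV1, LV2, experimental label, agreement flag.  ``predictions`` is a
    sequence of :class:`coamscreen.plsda.PredictionResult` (or any object
    with ``coam_value``, ``predicted_class`` and ``scores``), one per pair.
    """
    preds = list(predictions)
    if len(preds) != len(table.pairs):
        raise ContractError(
            f"{len(preds)} predictions for {len(table.pairs)} pairs"
        )
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["pair", "coam_value", "predicted", "lv1", "lv2", "experimental", "agreement"]
        )
        from .evaluation import agreement_flag  # local import avoids a cycle

        for pair, pred in zip(table.pairs, preds):
            lv = getattr(pred.scores, "lv", None) if pred.scores is not None else None
            exp = pair.experimental_label
            agree = (
                ""
                if exp is OutcomeLabel.UNKNOWN
                else ("Y" if agreement_flag(pred.predicted_class, exp) else "N")
            )
            w.writerow(
                [
                    pair.display_label,
                    "" if pred.coam_value is None else f"{pred.coam_value:.4f}",
                    LABEL_TO_CODE[pred.predicted_class],
                    "" if lv is None or len(lv) < 1 else f"{lv[0]:.6f}",
                    "" if lv is None or len(lv) < 2 else f"{lv[1]:.6f}",
                    _label_code(exp),
                    agree,
                ]
            )
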