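"""Compound library I/O and SMILES parsing.

A library is a list of :class:`CompoundRecord`: an identifier, a SMILES
string and a (possibly empty) set of NF-κB interaction labels.  An empty
label set means the compound's point of interaction in the pathway is
unknown; unknown compounds are kept in libraries because the clustering
protocol deliberately includes them.  The molecular-graph substrate for all
descriptor code is the RDKit ``Mol`` (2D, implicit hydrogens).
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from rdkit import Chem, RDLogger

# RDKit logs every parse failure to stderr; we raise instead.
RDLogger.DisableLog("rdApp.error")


class InteractionLabel(enum.Enum):
    """The six reported points of interaction in the NF-κB pathway.

    The pathway-point tag follows the numbered steps of the canonical
    cascade: IKK activation (1), IκB degradation/phosphorylation (2),
    nuclear translocation (3), DNA binding (4).  ROS-mediated interactions
    can act at any point and carry the tag ``"any"``.
    """

    ROS = "ROS"
    IKK_INHIBITION = "IKK_INHIBITION"
    IKB_DEG_INHIBITION = "IKB_DEG_INHIBITION"
    IKB_DEG_ACTIVATION = "IKB_DEG_ACTIVATION"
    TRANSLOCATION_INHIBITION = "TRANSLOCATION_INHIBITION"
    DNA_BINDING = "DNA_BINDING"

    @property
    def pathway_point(self) -> str:
        return _PATHWAY_POINT[self]


_PATHWAY_POINT = {
    InteractionLabel.ROS: "any",
    InteractionLabel.IKK_INHIBITION: "1",
    InteractionLabel.IKB_DEG_INHIBITION: "2",
    InteractionLabel.IKB_DEG_ACTIVATION: "2",
    InteractionLabel.TRANSLOCATION_INHIBITION: "3",
    InteractionLabel.DNA_BINDING: "4",
}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the string."""

    def __init__(self, smiles: str, reason: str = ""):
        self.smiles = smiles
        msg = f"could not parse SMILES {smiles!r}"
        if reason:
            msg += f": {reason}"
        super().__init__(msg)


class LibraryError(ValueError):
    """Raised for inconsistent compound libraries or label tables."""


@dataclass
class CompoundRecord:
    """One molecule of the library.

    ``labels`` is a set because four compounds of the original library act
    at more than one point of the pathway; an empty set marks an unknown
    interaction, not a seventh class.
    """

    compound_id: str
    smiles: str
    labels: frozenset[InteractionLabel] = frozenset()
    source_note: str = ""

    @property
    def is_labelled(self) -> bool:
        return len(self.labels) > 0


def parse_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string into an RDKit molecule (the graph model).

    Aromaticity is perceived and ring information is populated; hydrogens
    stay implicit so all counting descriptors operate on heavy atoms only.

    Raises
    ------
    SmilesParseError
        If the string is empty or not valid SMILES.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError(str(smiles), "empty input")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    Chem.GetSSSR(mol)  # ensure ring info is populated
    return mol


def _parse_label(value: str) -> InteractionLabel:
    try:
        return InteractionLabel(value.strip())
    except ValueError:
        valid = ", ".join(l.value for l in InteractionLabel)
        raise LibraryError(
            f"invalid interaction label {value!r}; expected one of: {valid}"
        ) from None


def read_labels_csv(path: str | Path) -> dict[str, set[InteractionLabel]]:
    """Read a label table: CSV with header ``compound_id,interaction``.

    Multi-label compounds appear on several rows; the result maps each
    compound id to the set of its labels.
    """
    labels: dict[str, set[InteractionLabel]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {
            "compound_id",
            "interaction",
        } <= set(reader.fieldnames):
            raise LibraryError(
                f"label file {path} must have columns compound_id,interaction"
            )
        for row in reader:
            cid = row["compound_id"].strip()
            labels.setdefault(cid, set()).add(_parse_label(row["interaction"]))
    return labels


def read_library(
    smiles_path: str | Path, labels_path: str | Path | None = None
) -> list[CompoundRecord]:
    """Read a ``.smi`` library (``SMILES<whitespace>ID`` per line) plus labels.

    Compounds absent from the label file get an empty label set (unknown
    interaction).  Output order equals input file order.

    Raises
    ------
    LibraryError
        On duplicate compound ids, label rows referencing missing
        compounds, or invalid label strings.
    SmilesParseError
        If any SMILES in the file does not parse.
    """
    records: list[CompoundRecord] = []
    seen: set[str] = set()
    with open(smiles_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise LibraryError(
                    f"{smiles_path}:{lineno}: expected 'SMILES<ws>ID', got {line!r}"
                )
            smiles, cid = parts[0], parts[1].strip()
            if cid in seen:
                raise LibraryError(f"duplicate compound_id {cid!r}")
            parse_smiles(smiles)  # validate
            seen.add(cid)
            records.append(CompoundRecord(compound_id=cid, smiles=smiles))

    if labels_path is not None:
        labels = read_labels_csv(labels_path)
        missing = sorted(set(labels) - seen)
        if missing:
            raise LibraryError(
                "label rows reference compounds absent from the SMILES file: "
                + ", ".join(missing)
            )
        records = [
            CompoundRecord(
                compound_id=r.compound_id,
                smiles=r.smiles,
                labels=frozenset(labels.get(r.compound_id, set())),
            )
            for r in records
        ]
    return records


def read_sdf(path: str | Path, id_property: str | None = None) -> list[CompoundRecord]:
    """Read a V2000 SDF; ids come from the title line or ``id_property``."""
    records: list[CompoundRecord] = []
    seen: set[str] = set()
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            raise SmilesParseError(f"<SDF record {i}>", "unreadable record")
        if id_property is not None:
            if not mol.HasProp(id_property):
                raise LibraryError(
                    f"SDF record {i} lacks the id property {id_property!r}"
                )
            cid = mol.GetProp(id_property)
        else:
            cid = mol.GetProp("_Name") or f"mol{i}"
        if cid in seen:
            raise LibraryError(f"duplicate compound_id {cid!r}")
        seen.add(cid)
        records.append(
            CompoundRecord(compound_id=cid, smiles=Chem.MolToSmiles(mol))
        )
    return records


def write_smiles_file(records: Iterable[CompoundRecord], path: str | Path) -> None:
    """Write records as a ``.smi`` file (one ``SMILES<TAB>ID`` per line)."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(f"{r.smiles}\t{r.compound_id}\n")


def write_labels_csv(records: Iterable[CompoundRecord], path: str | Path) -> None:
    """Write the label table of a library (one row per compound–label pair)."""
    rows = []
    for r in records:
        for label in sorted(r.labels, key=lambda l: l.value):
            rows.append({"compound_id": r.compound_id, "interaction": label.value})
    write_records_csv(rows, path, columns=["compound_id", "interaction"])


def write_records_csv(
    rows: Sequence[Mapping[str, object]],
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write a homogeneous list of row mappings as UTF-8 CSV.

    Column order is deterministic: the given ``columns``, or the key order
    of the first row.
    """
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(columns))
        writer.writeheader()
        for row in rows:
            writer.writerow(row)


def records_by_id(records: Iterable[CompoundRecord]) -> dict[str, CompoundRecord]:
    return {r.compound_id: r for r in records}
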