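"""Structure input and standardization.

Reads SDF (V2000) and SMILES files into :class:`MoleculeRecord` objects and
applies the standardization pipeline used throughout the package:

    fragment split -> drop water / salt fragments -> keep largest organic
    fragment -> neutralize charges -> aromatize -> add explicit hydrogens

The fixed order ensures that neutralization of discarded counter-ions never
affects the kept fragment. "Salt" means any fragment without a carbon atom,
plus a short list of common carbon-containing counter-ions (acetate,
trifluoroacetate, maleate, ...).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

# RDKit is chatty about kekulization etc. on malformed inputs; we log skips
# ourselves.
RDLogger.DisableLog("rdApp.error")


class ChemIOError(RuntimeError):
    """Fatal error while reading or standardizing structures."""


@dataclass
class MoleculeRecord:
    """One chemical structure with identifier and optional activity label."""

    id: str
    mol: Optional[Chem.Mol]
    label: Optional[int] = None
    source_line: int = -1
    invalid: bool = False
    invalid_reason: str = ""

    def require_valid(self) -> Chem.Mol:
        if self.invalid or self.mol is None:
            raise ChemIOError(
                f"record {self.id!r} is invalid ({self.invalid_reason or 'no structure'})"
            )
        return self.mol


# Common counter-ion fragments that contain carbon.  Canonical SMILES of both
# the charged and the neutral protonation state are listed, because inputs
# arrive in either form.
_SALT_SMILES = {
    "CC(=O)[O-]", "CC(=O)O",                    # acetate / acetic acid
    "O=C(O)C(F)(F)F", "[O-]C(=O)C(F)(F)F",      # trifluoroacetate
    "O=C([O-])C(F)(F)F",
    "O=C(O)/C=C\\C(=O)O", "O=C([O-])/C=C\\C(=O)[O-]",  # maleate
    "O=C(O)/C=C/C(=O)O", "O=C([O-])/C=C/C(=O)[O-]",    # fumarate
    "O=C(O)C(=O)O", "O=C([O-])C(=O)[O-]",       # oxalate
    "O=CO", "O=C[O-]",                          # formate
    "CS(=O)(=O)O", "CS(=O)(=O)[O-]",            # mesylate
    "Cc1ccc(S(=O)(=O)O)cc1", "Cc1ccc(S(=O)(=O)[O-])cc1",  # tosylate
    "O=C(O)CC(O)(CC(=O)O)C(=O)O",               # citrate (neutral)
    "OC(C(=O)O)C(O)C(=O)O",                     # tartrate (neutral)
}

_WATER_SMILES = {"O", "[OH2]", "[OH-]", "[H]O[H]"}

_UNCHARGER = rdMolStandardize.Uncharger()


def _canonical(mol: Chem.Mol) -> str:
    return Chem.MolToSmiles(mol)


def _is_water(frag: Chem.Mol) -> bool:
    return _canonical(Chem.RemoveHs(frag)) in _WATER_SMILES


def _has_carbon(frag: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() == 6 for a in frag.GetAtoms())


def _is_salt(frag: Chem.Mol) -> bool:
    if not _has_carbon(frag):
        return True
    return _canonical(Chem.RemoveHs(frag)) in _SALT_SMILES


def read_structures(path: str | Path, format: str) -> list[MoleculeRecord]:
    """Read an SDF or SMILES file into records, skipping unparsable entries.

    SMILES files hold one record per line: ``SMILES [id [label]]``; blank
    lines and lines starting with ``#`` are ignored.  SDF titles (or a
    running ordinal) provide ids.  Unparsable entries are logged and skipped;
    a file yielding zero parsable records is a fatal error.
    """
    path = Path(path)
    if not path.exists():
        raise ChemIOError(f"input file not found: {path}")
    fmt = format.lower()
    if fmt == "smiles":
        records = list(_read_smiles(path))
    elif fmt == "sdf":
        records = list(_read_sdf(path))
    else:
        raise ChemIOError(f"unknown format {format!r}; expected 'sdf' or 'smiles'")
    parsable = [r for r in records if r.mol is not None]
    if not parsable:
        raise ChemIOError(f"no parsable records in {path}")
    n_skip = len(records) - len(parsable)
    if n_skip:
        logger.warning("%d unparsable entries skipped in %s", n_skip, path)
    return _dedupe_ids(parsable)


def _read_smiles(path: Path) -> Iterable[MoleculeRecord]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smi = parts[0]
            rec_id = parts[1] if len(parts) > 1 else f"rec{lineno}"
            label = None
            if len(parts) > 2:
                try:
                    label = int(parts[2])
                except ValueError:
                    label = None
            if label is not None and label not in (0, 1):
                label = None
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                logger.warning("line %d: unparsable SMILES %r", lineno, smi)
            yield MoleculeRecord(id=rec_id, mol=mol, label=label, source_line=lineno)


def _read_sdf(path: Path) -> Iterable[MoleculeRecord]:
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            logger.warning("SDF entry %d unparsable", i)
            yield MoleculeRecord(id=f"sdf{i}", mol=None, source_line=i)
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        rec_id = name.strip() or f"sdf{i}"
        label = None
        for prop in ("label", "active", "activity"):
            if mol.HasProp(prop):
                try:
                    val = int(mol.GetProp(prop))
                except ValueError:
                    continue
                if val in (0, 1):
                    label = val
                break
        yield MoleculeRecord(id=rec_id, mol=mol, label=label, source_line=i)


def _dedupe_ids(records: list[MoleculeRecord]) -> list[MoleculeRecord]:
    # ids key all downstream joins; duplicates get an ordinal suffix
    seen: dict[str, int] = {}
    out = []
    for rec in records:
        n = seen.get(rec.id, 0)
        seen[rec.id] = n + 1
        if n:
            new_id = f"{rec.id}_{n + 1}"
            logger.warning("duplicate id %r renamed to %r", rec.id, new_id)
            rec = replace(rec, id=new_id)
        out.append(rec)
    return out


def standardize(record: MoleculeRecord) -> MoleculeRecord:
    """Standardize one record to a single neutral aromatic fragment.

    Water and salt fragments are removed, the largest organic fragment is
    kept (ties by molecular weight, then input order), charges are
    neutralized where a proton can safely be added or removed, aromaticity
    is perceived, and hydrogens are made explicit.  A record with no organic
    fragment (e.g. an inorganic salt) is flagged invalid instead of raising.
    """
    if record.mol is None:
        return replace(record, invalid=True, invalid_reason="no structure")
    frags = Chem.GetMolFrags(record.mol, asMols=True, sanitizeFrags=False)
    candidates = []
    fallback = []  # organic fragments that are themselves listed counter-ions
    for idx, frag in enumerate(frags):
        try:
            Chem.SanitizeMol(frag)
        except Exception:
            continue
        if not _has_carbon(frag):
            continue
        key = (frag.GetNumHeavyAtoms(), Descriptors.MolWt(frag), -idx, frag)
        if len(frags) > 1 and (_is_water(frag) or _is_salt(frag)):
            fallback.append(key)
            continue
        candidates.append(key)
    if not candidates:
        # e.g. sodium acetate: the only organic fragment is a listed
        # counter-ion — keep it rather than discarding the whole record
        candidates = fallback
    if not candidates:
        return replace(record, invalid=True, invalid_reason="no organic fragment")
    # largest heavy-atom count, then MW; -idx keeps earlier fragment on ties
    candidates.sort(key=lambda t: (t[0], t[1], t[2]), reverse=True)
    kept = candidates[0][3]

    kept = _UNCHARGER.uncharge(kept)
    Chem.SanitizeMol(kept)           # includes aromaticity perception
    kept = Chem.AddHs(kept)
    return replace(record, mol=kept, invalid=False, invalid_reason="")


def standardize_all(
    records: Sequence[MoleculeRecord],
) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Standardize a batch; returns (valid records, flagged records)."""
    good, bad = [], []
    for rec in records:
        out = standardize(rec)
        (bad if out.invalid else good).append(out)
    if bad:
        logger.warning("%d records flagged invalid during standardization", len(bad))
    return good, bad


def write_smiles(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    """Write standardized records as canonical SMILES with ids (and labels)."""
    with open(path, "w") as fh:
        for rec in records:
            mol = rec.require_valid()
            smi = Chem.MolToSmiles(Chem.RemoveHs(mol))
            cols = [smi, rec.id]
            if rec.label is not None:
                cols.append(str(rec.label))
            fh.write("\t".join(cols) + "\n")


def write_skip_report(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    """Tab-separated (id, reason) report of records flagged invalid."""
    with open(path, "w") as fh:
        fh.write("id\treason\n")
        for rec in records:
            fh.write(f"{rec.id}\t{rec.invalid_reason}\n")
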