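"""Fingerprints, physicochemical descriptors and feature-table assembly.

Three binary fingerprints are supported:

* ``MACCS`` — the 166 public MACCS substructure keys (RDKit numbering,
  key *i* stored at column *i-1*; RDKit's unused bit 0 is dropped).
* ``ECFP4`` — extended-connectivity fingerprint of diameter 4 (Morgan
  radius 2) folded to 1024 bits.
* ``ESTATE`` — binary presence vector over the 79 Hall–Kier
  electrotopological atom types.

A panel of 13 physicochemical/topological descriptors can be concatenated;
descriptor columns are z-scaled (zero mean, unit variance on the training
set) before concatenation so that distance-based methods are not dominated
by raw magnitudes.  Fingerprinting is a pure function of the standardized
structure: atom ordering of the input never changes the bits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator
from rdkit.Chem.EState import Fingerprinter as EStateFingerprinter

from .chemio import ChemIOError, MoleculeRecord

logger = logging.getLogger(__name__)

FP_LENGTHS = {"MACCS": 166, "ECFP4": 1024, "ESTATE": 79}

#: the 13-descriptor panel, in fixed order (substitutable via configuration)
DESCRIPTOR_FUNCS = {
    "MolWt": Descriptors.MolWt,
    "MolLogP": Descriptors.MolLogP,
    "TPSA": Descriptors.TPSA,
    "NumHDonors": Descriptors.NumHDonors,
    "NumHAcceptors": Descriptors.NumHAcceptors,
    "NumRotatableBonds": Descriptors.NumRotatableBonds,
    "RingCount": Descriptors.RingCount,
    "NumAromaticRings": Descriptors.NumAromaticRings,
    "HeavyAtomCount": Descriptors.HeavyAtomCount,
    "FractionCSP3": Descriptors.FractionCSP3,
    "MolMR": Descriptors.MolMR,
    "NumHeteroatoms": Descriptors.NumHeteroatoms,
    "NumValenceElectrons": Descriptors.NumValenceElectrons,
}
DESCRIPTOR_NAMES = list(DESCRIPTOR_FUNCS)

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)


@dataclass
class FingerprintVector:
    bits: np.ndarray
    fp_type: str

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.fp_type not in FP_LENGTHS:
            raise ValueError(f"unknown fingerprint type {self.fp_type!r}")
        if self.bits.shape != (FP_LENGTHS[self.fp_type],):
            raise ValueError(
                f"{self.fp_type} fingerprint must have length "
                f"{FP_LENGTHS[self.fp_type]}, got {self.bits.shape}"
            )
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("fingerprint bits must be 0/1")


@dataclass
class DescriptorVector:
    values: np.ndarray
    names: list[str] = field(default_factory=lambda: list(DESCRIPTOR_NAMES))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError("descriptor vector length mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("descriptor values must be finite")


def _featurizable(record: MoleculeRecord) -> Chem.Mol:
    mol = record.require_valid()
    # fingerprint definitions assume implicit hydrogens
    return Chem.RemoveHs(mol)


def fingerprint(record: MoleculeRecord, fp_type: str) -> FingerprintVector:
    """Compute one binary fingerprint for a standardized record."""
    if record.invalid:
        raise ChemIOError(f"cannot featurize invalid record {record.id!r}")
    mol = _featurizable(record)
    if fp_type == "MACCS":
        rk = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
        bits = np.zeros(166, dtype=np.uint8)
        for b in rk.GetOnBits():
            if b >= 1:
                bits[b - 1] = 1
    elif fp_type == "ECFP4":
        rk = _MORGAN.GetFingerprint(mol)
        bits = np.zeros(1024, dtype=np.uint8)
        for b in rk.GetOnBits():
            bits[b] = 1
    elif fp_type == "ESTATE":
        counts, _sums = EStateFingerprinter.FingerprintMol(mol)
        bits = (np.asarray(counts) > 0).astype(np.uint8)
    else:
        raise ValueError(f"unknown fingerprint type {fp_type!r}")
    return FingerprintVector(bits=bits, fp_type=fp_type)


def descriptors(record: MoleculeRecord) -> DescriptorVector:
    """Compute the 13-descriptor panel for a standardized record."""
    if record.invalid:
        raise ChemIOError(f"cannot featurize invalid record {record.id!r}")
    mol = _featurizable(record)
    values = np.array([f(mol) for f in DESCRIPTOR_FUNCS.values()], dtype=float)
    return DescriptorVector(values=values)


@dataclass
class FeatureTable:
    """Records-by-features matrix aligned to ids and optional binary labels.

    Column names carry their origin as a ``tag:name`` prefix — fingerprint
    bits are ``<fp_type>:<index>``, descriptors ``desc:<name>``.  Descriptor
    columns store the z-scaling parameters (training mean and sd) so that an
    external table can be scaled with the *training* parameters rather than
    its own.
    """

    ids: list[str]
    X: np.ndarray
    columns: list[str]
    labels: Optional[np.ndarray] = None
    scale_mean: dict = field(default_factory=dict)
    scale_sd: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != len(self.ids):
            raise ValueError("rows(X) must equal len(ids)")
        if self.X.shape[1] != len(self.columns):
            raise ValueError("cols(X) must equal len(columns)")
        if not np.isfinite(self.X).all():
            raise ValueError("feature table contains non-finite values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.ids),):
                raise ValueError("labels must align to rows")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be binary")

    @property
    def column_meta(self) -> list[str]:
        return [c.split(":", 1)[0] for c in self.columns]

    @property
    def n_records(self) -> int:
        return len(self.ids)

    def fingerprint_type(self) -> str:
        """The single fingerprint tag of the non-descriptor columns."""
        tags = {t for t in self.column_meta if t != "desc"}
        if len(tags) != 1:
            raise ValueError(f"expected one fingerprint tag, found {sorted(tags)}")
        return tags.pop()

    def fingerprint_matrix(self) -> np.ndarray:
        mask = [t != "desc" for t in self.column_meta]
        return self.X[:, np.asarray(mask, dtype=bool)]

    def subset(self, idx: np.ndarray) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            ids=[self.ids[i] for i in idx],
            X=self.X[idx],
            columns=list(self.columns),
            labels=None if self.labels is None else self.labels[idx],
            scale_mean=dict(self.scale_mean),
            scale_sd=dict(self.scale_sd),
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for col in self.columns:
                if col in self.scale_mean:
                    fh.write(
                        f"#scale\t{col}\t{self.scale_mean[col]:.17g}"
                        f"\t{self.scale_sd[col]:.17g}\n"
                    )
            header = ["id"] + self.columns + (["label"] if self.labels is not None else [])
            fh.write("\t".join(header) + "\n")
            for i, rec_id in enumerate(self.ids):
                cells = [rec_id] + [f"{v:.12g}" for v in self.X[i]]
                if self.labels is not None:
                    cells.append(str(int(self.labels[i])))
                fh.write("\t".join(cells) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureTable":
        scale_mean: dict = {}
        scale_sd: dict = {}
        with open(path) as fh:
            line = fh.readline()
            while line.startswith("#scale\t"):
                _, col, m, s = line.rstrip("\n").split("\t")
                scale_mean[col] = float(m)
                scale_sd[col] = float(s)
                line = fh.readline()
            header = line.rstrip("\n").split("\t")
            df = pd.read_csv(fh, sep="\t", names=header, dtype={"id": str})
        has_label = header[-1] == "label"
        columns = header[1 : -1 if has_label else len(header)]
        labels = df["label"].to_numpy(dtype=int) if has_label else None
        return cls(
            ids=df["id"].astype(str).tolist(),
            X=df[columns].to_numpy(dtype=float),
            columns=columns,
            labels=labels,
            scale_mean=scale_mean,
            scale_sd=scale_sd,
        )


def build_feature_table(
    records: Sequence[MoleculeRecord],
    fp_type: str,
    with_descriptors: bool = False,
    reference: Optional[FeatureTable] = None,
) -> FeatureTable:
    """Featurize records into a table, optionally appending scaled descriptors.

    When ``reference`` is given (a training table), its descriptor scaling
    parameters are reused; otherwise scaling is fitted on this set.  Records
    whose featurization fails are excluded with a log entry; an input with no
    valid record is fatal.
    """
    rows, ids, labels, any_label = [], [], [], False
    for rec in records:
        try:
            fp = fingerprint(rec, fp_type)
            desc = descriptors(rec) if with_descriptors else None
        except (ChemIOError, ValueError) as exc:
            logger.warning("record %r excluded: %s", getattr(rec, "id", "?"), exc)
            continue
        row = fp.bits.astype(float)
        if desc is not None:
            row = np.concatenate([row, desc.values])
        rows.append(row)
        ids.append(rec.id)
        labels.append(rec.label if rec.label is not None else -1)
        any_label = any_label or rec.label is not None
    if not rows:
        raise ChemIOError("no valid records to featurize")
    X = np.vstack(rows)
    columns = [f"{fp_type}:{i:04d}" for i in range(FP_LENGTHS[fp_type])]
    scale_mean: dict = {}
    scale_sd: dict = {}
    if with_descriptors:
        desc_cols = [f"desc:{n}" for n in DESCRIPTOR_NAMES]
        n_fp = FP_LENGTHS[fp_type]
        if reference is not None:
            scale_mean = {c: reference.scale_mean[c] for c in desc_cols}
            scale_sd = {c: reference.scale_sd[c] for c in desc_cols}
        else:
            mu = X[:, n_fp:].mean(axis=0)
            sd = X[:, n_fp:].std(axis=0)
            sd[sd == 0] = 1.0  # constant column: center only
            scale_mean = dict(zip(desc_cols, mu))
            scale_sd = dict(zip(desc_cols, sd))
        mu = np.array([scale_mean[c] for c in desc_cols])
        sd = np.array([scale_sd[c] for c in desc_cols])
        X[:, n_fp:] = (X[:, n_fp:] - mu) / sd
        columns += desc_cols
    label_arr = np.asarray(labels) if any_label else None
    if label_arr is not None and (label_arr < 0).any():
        raise ChemIOError("labels present for some records but missing for others")
    return FeatureTable(
        ids=ids, X=X, columns=columns, labels=label_arr,
        scale_mean=scale_mean, scale_sd=scale_sd,
    )
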