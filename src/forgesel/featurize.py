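"""SMILES featurization: ECFP6 + MACCS keys + 2D descriptors, fused into one matrix.

Each compound is described by three blocks concatenated in a fixed order:

* ``ECFP6`` — Morgan circular fingerprint of radius 3 (diameter 6) hashed to
  2048 bits, collapsed to presence/absence.
* ``MACCS`` — the 167 MACCS structural keys.
* ``RDKIT`` — a frozen, ordered list of 208 two-dimensional physicochemical
  descriptors (shipped in ``data/rdkit_descriptors_208.txt`` so the fused
  width never drifts with toolkit upgrades).

Default fused width is 2048 + 167 + 208 = 2423 columns.
"""

from __future__ import annotations

import csv
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator
from sklearn.base import BaseEstimator, TransformerMixin

ECFP6_BITS = 2048
MACCS_BITS = 167
RDKIT_WIDTH = 208
FUSED_WIDTH = ECFP6_BITS + MACCS_BITS + RDKIT_WIDTH

BLOCK_ORDER = ("ECFP6", "MACCS", "RDKIT")


class FeaturizationError(ValueError):
    """A SMILES string could not be parsed or featurized.

    Carries the offending compound id (when known) in ``compound_id``.
    """

    def __init__(self, message: str, compound_id: str | None = None):
        super().__init__(message)
        self.compound_id = compound_id


@dataclass(frozen=True)
class CompoundRecord:
    """One compound: opaque id, SMILES string, class label in {+1, -1}."""

    id: str
    smiles: str
    label: int

    def __post_init__(self):
        if self.label not in (+1, -1):
            raise ValueError(f"label must be +1 or -1, got {self.label!r}")


@dataclass
class FeatureBlock:
    """A named n_compounds x width block with per-column names."""

    name: str
    matrix: np.ndarray
    column_names: list[str]

    def __post_init__(self):
        if self.name not in BLOCK_ORDER:
            raise ValueError(f"unknown block name {self.name!r}")
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.column_names):
            raise ValueError("matrix shape inconsistent with column names")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]


@dataclass
class FusedFeatureMatrix:
    """Column-wise fusion of the (ECFP6, MACCS, RDKIT) blocks.

    ``block_boundaries`` maps each block name to its ``(start, stop)`` column
    span, so every fused column traces back to exactly one (block, index).
    """

    matrix: np.ndarray
    column_names: list[str]
    block_boundaries: dict[str, tuple[int, int]]
    labels: np.ndarray | None = None
    ids: list[str] | None = None
    manifest: dict = field(default_factory=dict)

    @property
    def n_compounds(self) -> int:
        return self.matrix.shape[0]

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def block(self, name: str) -> np.ndarray:
        start, stop = self.block_boundaries[name]
        return self.matrix[:, start:stop]

    def column_provenance(self, j: int) -> tuple[str, int]:
        """Map fused column ``j`` back to its (block name, within-block index)."""
        for name, (start, stop) in self.block_boundaries.items():
            if start <= j < stop:
                return name, j - start
        raise IndexError(j)

    def subset_rows(self, idx) -> "FusedFeatureMatrix":
        idx = np.asarray(idx)
        return FusedFeatureMatrix(
            matrix=self.matrix[idx],
            column_names=self.column_names,
            block_boundaries=dict(self.block_boundaries),
            labels=None if self.labels is None else self.labels[idx],
            ids=None if self.ids is None else [self.ids[i] for i in idx],
            manifest=dict(self.manifest),
        )


_DESCRIPTOR_NAMES: list[str] | None = None
_DESCRIPTOR_FNS: list | None = None


def rdkit_descriptor_names() -> list[str]:
    """The frozen, ordered 208-descriptor list shipped with the package."""
    global _DESCRIPTOR_NAMES
    if _DESCRIPTOR_NAMES is None:
        text = (
            resources.files("forgesel.data")
            .joinpath("rdkit_descriptors_208.txt")
            .read_text()
        )
        _DESCRIPTOR_NAMES = [ln for ln in text.splitlines() if ln.strip()]
        if len(_DESCRIPTOR_NAMES) != RDKIT_WIDTH:
            raise RuntimeError(
                f"descriptor list has {len(_DESCRIPTOR_NAMES)} names, "
                f"expected {RDKIT_WIDTH}"
            )
    return _DESCRIPTOR_NAMES


def _descriptor_fns():
    global _DESCRIPTOR_FNS
    if _DESCRIPTOR_FNS is None:
        by_name = dict(Descriptors.descList)
        missing = [n for n in rdkit_descriptor_names() if n not in by_name]
        if missing:
            raise RuntimeError(f"descriptors missing from toolkit: {missing[:5]}")
        _DESCRIPTOR_FNS = [by_name[n] for n in rdkit_descriptor_names()]
    return _DESCRIPTOR_FNS


def _mol_from_smiles(smiles: str, compound_id: str | None = None) -> Chem.Mol:
    # Empty SMILES technically parses to an empty molecule; treat as an error
    # so silent all-zero rows can never enter a decoy set.
    if not isinstance(smiles, str) or smiles.strip() == "":
        raise FeaturizationError("empty SMILES", compound_id)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise FeaturizationError(f"unparsable SMILES: {smiles!r}", compound_id)
    return mol


def compute_ecfp6(
    smiles: str, n_bits: int = ECFP6_BITS, compound_id: str | None = None
) -> np.ndarray:
    """Radius-3 (diameter-6) circular fingerprint hashed to ``n_bits`` binary bits."""
    if n_bits <= 0:
        raise ValueError("n_bits must be positive")
    mol = _mol_from_smiles(smiles, compound_id)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    arr[list(fp.GetOnBits())] = 1
    return arr


def compute_maccs(smiles: str, compound_id: str | None = None) -> np.ndarray:
    """The 167 MACCS structural keys as a binary vector."""
    mol = _mol_from_smiles(smiles, compound_id)
    fp = MACCSkeys.GenMACCSKeys(mol)
    arr = np.zeros(MACCS_BITS, dtype=np.uint8)
    arr[list(fp.GetOnBits())] = 1
    return arr


def compute_rdkit_block(smiles: str, compound_id: str | None = None) -> np.ndarray:
    """Evaluate the frozen 208-descriptor list; non-finite values become 0."""
    mol = _mol_from_smiles(smiles, compound_id)
    out = np.empty(RDKIT_WIDTH, dtype=np.float64)
    names = rdkit_descriptor_names()
    for j, fn in enumerate(_descriptor_fns()):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                v = float(fn(mol))
        except Exception:
            v = np.nan
        if not np.isfinite(v):
            warnings.warn(
                f"descriptor {names[j]} non-finite for {compound_id or smiles!r}; "
                "replaced by 0",
                RuntimeWarning,
                stacklevel=2,
            )
            v = 0.0
        out[j] = v
    return out


def _fused_column_names(n_bits: int = ECFP6_BITS) -> list[str]:
    names = [f"e{i}" for i in range(n_bits)]
    names += [f"m{i}" for i in range(MACCS_BITS)]
    names += [f"r_{n}" for n in rdkit_descriptor_names()]
    return names


def fuse_blocks(
    blocks,
    labels=None,
    ids=None,
) -> FusedFeatureMatrix:
    """Concatenate (ECFP6, MACCS, RDKIT) blocks column-wise in that fixed order."""
    blocks = list(blocks)
    if tuple(b.name for b in blocks) != BLOCK_ORDER:
        raise ValueError(f"blocks must be ordered {BLOCK_ORDER}")
    n_rows = {b.matrix.shape[0] for b in blocks}
    if len(n_rows) != 1:
        raise ValueError(f"row-count mismatch across blocks: {sorted(n_rows)}")
    boundaries: dict[str, tuple[int, int]] = {}
    start = 0
    names: list[str] = []
    for b in blocks:
        boundaries[b.name] = (start, start + b.width)
        start += b.width
        names.extend(b.column_names)
    matrix = np.hstack([b.matrix.astype(np.float64) for b in blocks])
    return FusedFeatureMatrix(
        matrix=matrix,
        column_names=names,
        block_boundaries=boundaries,
        labels=None if labels is None else np.asarray(labels),
        ids=list(ids) if ids is not None else None,
    )


class MoleculeFeaturizer(TransformerMixin, BaseEstimator):
    """Transform SMILES strings into the fused (ECFP6 | MACCS | RDKIT) matrix.

    Parameters
    ----------
    n_bits : int
        Hash width of the circular-fingerprint block.
    standardize : bool
        Z-score the descriptor span using statistics of the *fitted* rows
        only. Binary bits are left untouched. On by default: unscaled
        descriptors (molecular weight, surface areas, ...) would otherwise
        dominate the 0/1 fingerprint bits downstream.

    The transformer is stateless apart from the descriptor-span mean/scale
    learned in :meth:`fit`.
    """

    def __init__(self, n_bits: int = ECFP6_BITS, standardize: bool = True):
        self.n_bits = n_bits
        self.standardize = standardize

    def _raw_matrix(self, smiles_list, ids=None) -> np.ndarray:
        ids = ids if ids is not None else [None] * len(smiles_list)
        rows = []
        for smi, cid in zip(smiles_list, ids):
            e = compute_ecfp6(smi, self.n_bits, compound_id=cid)
            m = compute_maccs(smi, compound_id=cid)
            r = compute_rdkit_block(smi, compound_id=cid)
            rows.append(np.concatenate([e.astype(np.float64), m.astype(np.float64), r]))
        if not rows:
            return np.empty((0, self.n_bits + MACCS_BITS + RDKIT_WIDTH))
        return np.vstack(rows)

    def fit(self, X, y=None):
        """Learn descriptor-span standardization statistics from SMILES in X."""
        X = list(X)
        mat = self._raw_matrix(X)
        start = self.n_bits + MACCS_BITS
        desc = mat[:, start:]
        self.desc_mean_ = desc.mean(axis=0) if len(X) else np.zeros(RDKIT_WIDTH)
        scale = desc.std(axis=0) if len(X) else np.ones(RDKIT_WIDTH)
        scale[scale == 0] = 1.0
        self.desc_scale_ = scale
        self.n_features_out_ = self.n_bits + MACCS_BITS + RDKIT_WIDTH
        return self

    def transform(self, X) -> np.ndarray:
        mat = self._raw_matrix(list(X))
        if self.standardize:
            if not hasattr(self, "desc_mean_"):
                raise RuntimeError("featurizer not fitted; call fit() first")
            start = self.n_bits + MACCS_BITS
            mat[:, start:] = (mat[:, start:] - self.desc_mean_) / self.desc_scale_
        return mat

    def fused_column_names(self) -> list[str]:
        return _fused_column_names(self.n_bits)


def featurize_compounds(
    records,
    n_bits: int = ECFP6_BITS,
    standardize: bool = True,
    fit_records=None,
) -> FusedFeatureMatrix:
    """Featurize CompoundRecords into a FusedFeatureMatrix.

    ``fit_records`` optionally supplies the rows whose statistics standardize
    the descriptor span (training rows); defaults to ``records`` themselves.
    """
    records = list(records)
    ft = MoleculeFeaturizer(n_bits=n_bits, standardize=standardize)
    ft.fit([r.smiles for r in (fit_records if fit_records is not None else records)])
    mat = ft.transform([r.smiles for r in records])
    boundaries = {
        "ECFP6": (0, n_bits),
        "MACCS": (n_bits, n_bits + MACCS_BITS),
        "RDKIT": (n_bits + MACCS_BITS, n_bits + MACCS_BITS + RDKIT_WIDTH),
    }
    return FusedFeatureMatrix(
        matrix=mat,
        column_names=_fused_column_names(n_bits),
        block_boundaries=boundaries,
        labels=np.array([r.label for r in records]),
        ids=[r.id for r in records],
        manifest={
            "standardize": standardize,
            "descriptor_list_sha256": _descriptor_list_checksum(),
            "desc_mean": ft.desc_mean_.tolist(),
            "desc_scale": ft.desc_scale_.tolist(),
        },
    )


def _descriptor_list_checksum() -> str:
    joined = "\n".join(rdkit_descriptor_names())
    return hashlib.sha256(joined.encode()).hexdigest()


_LABEL_TOKENS = {"active": +1, "1": +1, "+1": +1, "inactive": -1, "0": -1, "-1": -1}


def read_compounds_csv(path) -> list[CompoundRecord]:
    """Read a compound table with header ``id,smiles,label``."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "smiles", "label"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"compound CSV must have columns {sorted(required)}")
        for row in reader:
            token = row["label"].strip().lower()
            if token not in _LABEL_TOKENS:
                raise ValueError(f"unrecognized label token {row['label']!r}")
            records.append(
                CompoundRecord(
                    id=row["id"].strip(),
                    smiles=row["smiles"].strip(),
                    label=_LABEL_TOKENS[token],
                )
            )
    return records


def write_features_tsv(fm: FusedFeatureMatrix, path, manifest_path=None) -> None:
    """Write the fused matrix as TSV plus a JSON sidecar manifest."""
    with open(path, "w") as fh:
        header = ["id", "label", *fm.column_names] if fm.ids else fm.column_names
        fh.write("\t".join(header) + "\n")
        for i in range(fm.n_compounds):
            vals = [format(v, ".10g") for v in fm.matrix[i]]
            if fm.ids:
                lbl = "" if fm.labels is None else str(int(fm.labels[i]))
                fh.write("\t".join([fm.ids[i], lbl, *vals]) + "\n")
            else:
                fh.write("\t".join(vals) + "\n")
    manifest = {
        "block_boundaries": {k: list(v) for k, v in fm.block_boundaries.items()},
        **fm.manifest,
    }
    mpath = manifest_path or (str(path) + ".manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def read_features_tsv(path, manifest_path=None) -> FusedFeatureMatrix:
    """Read a feature TSV written by :func:`write_features_tsv`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        has_meta = header[:2] == ["id", "label"]
        col_names = header[2:] if has_meta else header
        ids, labels, rows = [], [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if has_meta:
                ids.append(parts[0])
                labels.append(int(parts[1]) if parts[1] else 0)
                rows.append([float(x) for x in parts[2:]])
            else:
                rows.append([float(x) for x in parts])
    matrix = np.array(rows, dtype=np.float64)
    mpath = manifest_path or (str(path) + ".manifest.json")
    boundaries = None
    manifest = {}
    try:
        with open(mpath) as fh:
            manifest = json.load(fh)
        boundaries = {k: tuple(v) for k, v in manifest["block_boundaries"].items()}
    except FileNotFoundError:
        boundaries = {"ALL": (0, matrix.shape[1])}
    return FusedFeatureMatrix(
        matrix=matrix,
        column_names=col_names,
        block_boundaries=boundaries,
        labels=np.array(labels) if has_meta else None,
        ids=ids if has_meta else None,
        manifest=manifest,
    )
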