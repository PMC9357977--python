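"""Synthetic active/decoy datasets with planted informative columns.

The generator emulates the structure of a fused fingerprint/descriptor table
for a virtual-screening benchmark: ``m`` active compounds and ``ratio * m``
decoys (default 1:3, the usual active:decoy design), binary fingerprint-like
columns plus a tail of real-valued descriptor-like columns, and a planted
subset of class-informative columns. Informative binary columns fire at
``active_rate`` for actives and ``decoy_rate`` for decoys; background binary
columns fire at ``background_rate`` for everyone; informative real columns
are Normal(effect_shift, 1) for actives and Normal(0, 1) otherwise.

Decoys are drawn from a larger candidate pool by sampling ``ratio * m``
records uniformly *without replacement*, mirroring how a decoy set is
subsampled from a generated pool.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np

from .featurize import CompoundRecord, FusedFeatureMatrix


@dataclass(frozen=True)
class PlantedDatasetSpec:
    """Study-design parameters of the planted-feature generator."""

    m: int = 94
    decoy_ratio: int = 3
    d: int = 500
    n_informative: int = 20
    active_rate: float = 0.6
    decoy_rate: float = 0.2
    background_rate: float = 0.1
    n_real_cols: int = 40
    effect_shift: float = 1.0
    pool_factor: float = 2.0
    seed: int | None = None

    def __post_init__(self):
        for name in ("active_rate", "decoy_rate", "background_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_informative > self.d:
            raise ValueError("n_informative cannot exceed d")
        if self.decoy_ratio < 1:
            raise ValueError("decoy_ratio must be >= 1")
        if self.n_real_cols > self.d:
            raise ValueError("n_real_cols cannot exceed d")
        if self.pool_factor < 1.0:
            raise ValueError("pool_factor must be >= 1")

    def null(self) -> "PlantedDatasetSpec":
        """The matched no-effect design: no column separates the classes."""
        return replace(
            self,
            active_rate=self.background_rate,
            decoy_rate=self.background_rate,
            effect_shift=0.0,
        )

    @classmethod
    def full_width(cls, **overrides) -> "PlantedDatasetSpec":
        """Fused-width profile (d=2423, 208 descriptor-like columns)."""
        base = dict(d=2423, n_real_cols=208, n_informative=40)
        base.update(overrides)
        return cls(**base)


@dataclass
class DecoyPool:
    """Candidate decoy feature rows from which the decoy set is subsampled."""

    records: np.ndarray

    @property
    def size(self) -> int:
        return len(self.records)


def sample_decoys(pool: DecoyPool, m: int, ratio: int = 3, seed=None) -> np.ndarray:
    """Draw exactly ``ratio * m`` distinct rows from the pool, uniformly
    without replacement."""
    if m < 1:
        raise ValueError("m must be positive")
    need = ratio * m
    if pool.size < need:
        raise ValueError(
            f"decoy pool too small: need {need} records, pool has {pool.size}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(pool.size, size=need, replace=False)
    return pool.records[idx]


def _draw_rows(rng, n_rows, spec: PlantedDatasetSpec, informative, is_active: bool):
    n_binary = spec.d - spec.n_real_cols
    X = np.empty((n_rows, spec.d))
    # binary block
    rates = np.full(n_binary, spec.background_rate)
    inf_binary = informative[informative < n_binary]
    rates[inf_binary] = spec.active_rate if is_active else spec.decoy_rate
    X[:, :n_binary] = rng.random((n_rows, n_binary)) < rates
    # real block
    means = np.zeros(spec.n_real_cols)
    inf_real = informative[informative >= n_binary] - n_binary
    if is_active:
        means[inf_real] = spec.effect_shift
    X[:, n_binary:] = rng.standard_normal((n_rows, spec.n_real_cols)) + means
    return X


def generate_planted(spec: PlantedDatasetSpec):
    """Generate the planted dataset.

    Returns ``(FusedFeatureMatrix, informative_indices)``; actives first
    (label +1), then the decoys (label -1) subsampled without replacement
    from a ``pool_factor``-times larger candidate pool.
    """
    rng = np.random.default_rng(spec.seed)
    n_binary = spec.d - spec.n_real_cols
    informative = np.sort(rng.choice(spec.d, size=spec.n_informative, replace=False))

    X_pos = _draw_rows(rng, spec.m, spec, informative, is_active=True)
    pool_size = int(np.ceil(spec.pool_factor * spec.decoy_ratio * spec.m))
    pool = DecoyPool(records=_draw_rows(rng, pool_size, spec, informative, is_active=False))
    X_neg = sample_decoys(
        pool, spec.m, spec.decoy_ratio, seed=rng.integers(0, 2**31 - 1)
    )

    X = np.vstack([X_pos, X_neg])
    y = np.concatenate([np.ones(spec.m), -np.ones(spec.decoy_ratio * spec.m)]).astype(int)
    ids = [f"A{i:05d}" for i in range(spec.m)] + [
        f"D{i:05d}" for i in range(spec.decoy_ratio * spec.m)
    ]
    names = [f"b{i}" for i in range(n_binary)] + [f"x{i}" for i in range(spec.n_real_cols)]
    fm = FusedFeatureMatrix(
        matrix=X,
        column_names=names,
        block_boundaries={"BINARY": (0, n_binary), "REAL": (n_binary, spec.d)},
        labels=y,
        ids=ids,
        manifest={"generator": "planted", "spec": {**spec.__dict__}},
    )
    return fm, informative


# Public canonical SMILES for compounds commonly reported active against the
# relevant targets (flavonoids and phytosterols), plus simple presumed-inactive
# molecules. These are test fixtures for featurization round-trips, not a
# reconstruction of any screening dataset.
_FIXTURES = [
    ("quercetin", "O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12", +1),
    ("kaempferol", "O=c1c(O)c(-c2ccc(O)cc2)oc2cc(O)cc(O)c12", +1),
    ("isorhamnetin", "COc1cc(-c2oc3cc(O)cc(O)c3c(=O)c2O)ccc1O", +1),
    (
        "naringin",
        "O=C1CC(c2ccc(O)cc2)Oc2cc(OC3OC(CO)C(O)C(O)C3OC3OC(C)C(O)C(O)C3O)cc(O)c21",
        +1,
    ),
    (
        "beta-sitosterol",
        "CCC(CCC(C)C1CCC2C1(C)CCC1C2CC=C2CC(O)CCC21C)C(C)C",
        +1,
    ),
    (
        "stigmasterol",
        "CCC(C=CC(C)C1CCC2C1(C)CCC1C2CC=C2CC(O)CCC21C)C(C)C",
        +1,
    ),
    (
        "icariin",
        "COc1ccc(-c2oc3cc(OC4OC(CO)C(O)C(O)C4O)cc(O)c3c(=O)c2OC2OC(C)C(O)C(O)C2O)cc1",
        +1,
    ),
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O", -1),
    ("caffeine", "Cn1c(=O)c2c(ncn2C)n(C)c1=O", -1),
    ("ibuprofen", "CC(C)Cc1ccc(C(C)C(=O)O)cc1", -1),
    ("benzoic-acid", "O=C(O)c1ccccc1", -1),
    ("nicotine", "CN1CCCC1c1cccnc1", -1),
]


def fixture_compounds() -> list[CompoundRecord]:
    """A small, stable list of parseable compound records for round-trip tests."""
    return [CompoundRecord(id=i, smiles=s, label=l) for i, s, l in _FIXTURES]


def fixture_checksum() -> str:
    """SHA-256 over the canonical `id,smiles,label` serialization of the fixtures."""
    text = "\n".join(f"{i},{s},{l:+d}" for i, s, l in _FIXTURES)
    return hashlib.sha256(text.encode()).hexdigest()


def write_compounds_csv(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("id,smiles,label\n")
        for r in records:
            fh.write(f"{r.id},{r.smiles},{'active' if r.label == 1 else 'inactive'}\n")
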