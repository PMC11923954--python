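"""Per-compound feature construction: fingerprints, embeddings, feature sets.

Each compound is represented either by chemical structure — binary molecular
fingerprints in one or more of three systems (MACCS: 166 bits, PubChem-style
substructure keys: 881 bits, ECFP6: 1024 bits) — or by a continuous text
embedding of its free-text description (1536-d "small" or 3072-d "large"
model).  The nine feature sets benchmarked downstream are the seven
non-empty combinations of the three fingerprint systems plus the two
embedding sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from ._pubchem_fp import PUBCHEM_FP_LENGTH, pubchem_fingerprint

__all__ = [
    "FINGERPRINT_SYSTEMS",
    "FINGERPRINT_LENGTHS",
    "EMBEDDING_MODELS",
    "FingerprintVector",
    "EmbeddingVector",
    "FeatureSet",
    "EmbeddingProvider",
    "compute_fingerprint",
    "concat_features",
    "embed_description",
    "enumerate_feature_sets",
    "assemble_feature_matrix",
]

#: Fixed concatenation order of the three fingerprint systems.
FINGERPRINT_SYSTEMS: tuple[str, ...] = ("MACCS", "PubChem", "ECFP6")

#: MACCS emits its 166 defined keys (the common 167-position layout keeps
#: index 0 unused; it is dropped here).
FINGERPRINT_LENGTHS: dict[str, int] = {"MACCS": 166, "PubChem": 881, "ECFP6": 1024}

EMBEDDING_MODELS: dict[str, int] = {"small": 1536, "large": 3072}

_ECFP6_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=1024)


@dataclass(frozen=True)
class FingerprintVector:
    system: str
    bits: np.ndarray

    def __post_init__(self) -> None:
        expected = FINGERPRINT_LENGTHS[self.system]
        if self.bits.shape != (expected,):
            raise ValueError(
                f"{self.system} fingerprint must have length {expected}, "
                f"got {self.bits.shape}"
            )

    def __len__(self) -> int:
        return self.bits.size


@dataclass(frozen=True)
class EmbeddingVector:
    model: str
    values: np.ndarray

    def __post_init__(self) -> None:
        expected = EMBEDDING_MODELS[self.model]
        if self.values.shape != (expected,):
            raise ValueError(
                f"{self.model} embedding must have dim {expected}, got {self.values.shape}"
            )

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class FeatureSet:
    """One of the nine benchmarked input representations."""

    id: str
    kind: str  # "structure" | "description"
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind == "structure":
            if not self.members or not set(self.members) <= set(FINGERPRINT_SYSTEMS):
                raise ValueError("structure sets must be non-empty fingerprint subsets")
        elif self.kind == "description":
            if len(self.members) != 1 or self.members[0] not in EMBEDDING_MODELS:
                raise ValueError("description sets hold exactly one embedding model")
        else:
            raise ValueError(f"unknown feature-set kind {self.kind!r}")

    @property
    def n_features(self) -> int:
        if self.kind == "structure":
            return sum(FINGERPRINT_LENGTHS[m] for m in self.members)
        return EMBEDDING_MODELS[self.members[0]]

    @property
    def is_binary(self) -> bool:
        return self.kind == "structure"


class EmbeddingProvider(Protocol):
    """Anything that can turn description text into an embedding vector."""

    def embed(self, text: str, model: str = "small") -> np.ndarray: ...


def _mol_from_smiles(smiles: str, compound_id: str | None = None) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        who = f" for compound {compound_id!r}" if compound_id else ""
        raise ValueError(f"unparsable SMILES {smiles!r}{who}")
    return mol


def compute_fingerprint(
    smiles: str, system: str, compound_id: str | None = None
) -> FingerprintVector:
    """Binary fingerprint of the molecule in the named system.

    Deterministic for a given canonical structure: equivalent SMILES
    spellings of the same molecule give identical bits.
    """
    if system not in FINGERPRINT_LENGTHS:
        raise ValueError(f"unknown fingerprint system {system!r}")
    mol = _mol_from_smiles(smiles, compound_id)
    if system == "MACCS":
        full = MACCSkeys.GenMACCSKeys(mol)  # 167 positions, index 0 unused
        bits = np.array(full, dtype=np.uint8)[1:]
    elif system == "ECFP6":
        bits = np.array(_ECFP6_GEN.GetFingerprint(mol), dtype=np.uint8)
    else:  # PubChem-style substructure keys
        bits = pubchem_fingerprint(mol)
    return FingerprintVector(system=system, bits=bits)


def concat_features(
    feature_set: FeatureSet, vectors: dict[str, FingerprintVector]
) -> np.ndarray:
    """Concatenate member fingerprints in the fixed MACCS, PubChem, ECFP6 order."""
    if feature_set.kind != "structure":
        raise ValueError("concat_features applies to structure feature sets")
    parts = []
    for system in FINGERPRINT_SYSTEMS:
        if system in feature_set.members:
            if system not in vectors:
                raise ValueError(f"missing member fingerprint {system}")
            parts.append(vectors[system].bits)
    return np.concatenate(parts)


def embed_description(
    description: str, model: str, provider: EmbeddingProvider
) -> EmbeddingVector | None:
    """Embed a compound description; empty text flags the compound incomplete.

    Returns ``None`` for empty/whitespace descriptions — such compounds are
    excluded from description-based modelling rather than failing the run.
    """
    if model not in EMBEDDING_MODELS:
        raise ValueError(f"unknown embedding model {model!r}")
    if not description or not description.strip():
        return None
    values = np.asarray(provider.embed(description, model=model), dtype=float)
    return EmbeddingVector(model=model, values=values)


def enumerate_feature_sets() -> list[FeatureSet]:
    """The nine feature sets: 7 fingerprint combinations + 2 embedding sizes.

    Order and ids are stable across calls: single systems first, then pairs,
    then the triple (subset order by system position), then embeddings.
    """
    sets: list[FeatureSet] = []
    n = len(FINGERPRINT_SYSTEMS)
    for size in range(1, n + 1):
        for mask in range(1, 2**n):
            members = tuple(
                FINGERPRINT_SYSTEMS[i] for i in range(n) if mask >> i & 1
            )
            if len(members) != size:
                continue
            sets.append(
                FeatureSet(id="+".join(members), kind="structure", members=members)
            )
    for model in EMBEDDING_MODELS:
        sets.append(
            FeatureSet(id=f"embedding-{model}", kind="description", members=(model,))
        )
    return sets


def assemble_feature_matrix(
    compounds: pd.DataFrame,
    feature_set: FeatureSet,
    provider: EmbeddingProvider | None = None,
    *,
    smiles_col: str = "smiles",
    description_col: str = "description",
    id_col: str = "compound_id",
) -> tuple[np.ndarray, list[str]]:
    """Build the (n_retained, n_features) matrix for one feature set.

    Compounds with incomplete features for the set (unparsable SMILES for
    structure sets; empty descriptions for description sets) are dropped;
    the retained compound ids are returned alongside the matrix so callers
    can audit retention.  Raises if no compound survives.
    """
    rows: list[np.ndarray] = []
    retained: list[str] = []
    for _, row in compounds.iterrows():
        cid = str(row[id_col])
        try:
            if feature_set.kind == "structure":
                vectors = {
                    s: compute_fingerprint(row[smiles_col], s, compound_id=cid)
                    for s in feature_set.members
                }
                vec = concat_features(feature_set, vectors).astype(float)
            else:
                if provider is None:
                    raise ValueError("embedding provider required for description sets")
                desc = row.get(description_col, "")
                emb = embed_description(
                    "" if pd.isna(desc) else str(desc),
                    feature_set.members[0],
                    provider,
                )
                if emb is None:
                    continue
                vec = emb.values
        except ValueError as err:
            if "unparsable SMILES" in str(err):
                continue
            raise
        rows.append(vec)
        retained.append(cid)
    if not rows:
        raise ValueError(f"no compound has complete features for set {feature_set.id}")
    return np.vstack(rows), retained


def audit_feature_completeness(
    compounds: pd.DataFrame,
    provider: EmbeddingProvider | None = None,
    *,
    smiles_col: str = "smiles",
    description_col: str = "description",
    id_col: str = "compound_id",
) -> pd.DataFrame:
    """Per-compound flags for structure/description availability.

    Mirrors the modelling rule that only compounds with *both* feature types
    enter two-channel (structure + description) training.
    """
    records = []
    for _, row in compounds.iterrows():
        has_structure = Chem.MolFromSmiles(str(row[smiles_col])) is not None
        desc = row.get(description_col, "")
        has_description = not (pd.isna(desc) or not str(desc).strip())
        records.append(
            {
                id_col: str(row[id_col]),
                "has_structure": has_structure,
                "has_description": has_description,
                "modelable": has_structure and has_description,
            }
        )
    return pd.DataFrame(records)
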