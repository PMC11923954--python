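"""Virtual screening: rank an external compound library with a trained ensemble.

Library compounds are featurized through the same structure + description
pipeline as the training set; compounds lacking either feature channel are
excluded and counted in an audit.  Predicted responses are on the log2
normalized-PGCC scale, so the most negative prediction (strongest predicted
PGCC inhibition) receives rank 1.  Compounds already present in the training
library can be excluded, matched by canonical SMILES with compound-id
fallback (name strings are unreliable keys).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .ensemble import DeployedEnsemble
from .features import EmbeddingProvider, FeatureSet, assemble_feature_matrix

__all__ = ["ScreenAudit", "score_library", "select_top"]


@dataclass
class ScreenAudit:
    """Bookkeeping of which library compounds were scored and why not."""

    n_library: int
    n_scored: int
    missing_structure: list[str] = field(default_factory=list)
    missing_description: list[str] = field(default_factory=list)
    excluded_training: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [{"compound_id": c, "reason": "missing_structure"} for c in self.missing_structure]
            + [{"compound_id": c, "reason": "missing_description"} for c in self.missing_description]
            + [{"compound_id": c, "reason": "in_training_library"} for c in self.excluded_training]
        )
        return pd.DataFrame(rows, columns=["compound_id", "reason"])


def _canonical_smiles(smiles: str) -> str | None:
    mol = Chem.MolFromSmiles(str(smiles))
    return Chem.MolToSmiles(mol) if mol is not None else None


def score_library(
    model: DeployedEnsemble,
    library: pd.DataFrame,
    structure_set: FeatureSet,
    description_set: FeatureSet,
    provider: EmbeddingProvider,
    training_library: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, ScreenAudit]:
    """Score and rank every library compound with complete features.

    Returns a ranked table (compound_id, smiles, predicted_y, rank), sorted
    ascending by predicted response (rank 1 = strongest predicted PGCC
    inhibition), with ties broken deterministically by compound_id, plus a
    :class:`ScreenAudit`.  ``training_library`` (if given) removes compounds
    already screened, matching by canonical SMILES and falling back to
    compound_id.
    """
    lib = library.copy()
    lib["compound_id"] = lib["compound_id"].astype(str)
    audit = ScreenAudit(n_library=len(lib), n_scored=0)

    if training_library is not None:
        train_smiles = {
            s
            for s in (
                _canonical_smiles(x) for x in training_library["smiles"].astype(str)
            )
            if s is not None
        }
        train_ids = set(training_library["compound_id"].astype(str))
        keep = []
        for row in lib.itertuples():
            canon = _canonical_smiles(row.smiles)
            if (canon is not None and canon in train_smiles) or row.compound_id in train_ids:
                audit.excluded_training.append(row.compound_id)
            else:
                keep.append(row.Index)
        lib = lib.loc[keep]

    # feature completeness per channel
    desc = lib.get("description")
    has_desc = (
        desc.notna() & desc.astype(str).str.strip().astype(bool)
        if desc is not None
        else pd.Series(False, index=lib.index)
    )
    has_struct = lib["smiles"].astype(str).map(lambda s: _canonical_smiles(s) is not None)
    audit.missing_structure = lib.loc[~has_struct, "compound_id"].tolist()
    audit.missing_description = lib.loc[has_struct & ~has_desc, "compound_id"].tolist()
    scorable = lib[has_struct & has_desc]
    if scorable.empty:
        raise ValueError("no library compound has both structure and description features")

    X_s, ids_s = assemble_feature_matrix(scorable, structure_set)
    X_d, ids_d = assemble_feature_matrix(scorable, description_set, provider=provider)
    if ids_s != ids_d:  # pragma: no cover - completeness already enforced
        raise RuntimeError("feature pipelines retained different compound sets")

    pred = model.predict(X_s, X_d)
    out = scorable.set_index("compound_id").loc[ids_s].reset_index()
    out = out[["compound_id", "smiles"]].assign(predicted_y=pred)
    out = out.sort_values(
        ["predicted_y", "compound_id"], ascending=[True, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    audit.n_scored = len(out)
    return out, audit


def select_top(ranked: pd.DataFrame, k: int) -> pd.DataFrame:
    """First k candidates by rank (k = 0 gives an empty list)."""
    if k < 0 or k > len(ranked):
        raise ValueError(f"k={k} out of range for {len(ranked)} ranked compounds")
    return ranked.nsmallest(k, "rank").sort_values("rank").reset_index(drop=True)
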