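"""Pluggable molecular featurization behind a chemistry-free core.

The core pipeline consumes plain numeric feature tables; molecules
enter through this boundary. Two descriptor families are supported when
RDKit is installed (the ``chem`` extra): hashed circular fingerprints
(ECFP-style Morgan bits, radius 3 / 2048 bits by default) and the full
RDKit physicochemical descriptor collection. SMILES are canonicalized
before featurization; unparseable rows are dropped with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .errors import CapabilityError, InputError

logger = logging.getLogger(__name__)

__all__ = ["FeaturizerSpec", "featurize"]


@dataclass(frozen=True)
class FeaturizerSpec:
    kind: Literal["ecfp", "physchem", "none"] = "none"
    radius: int = 3
    n_bits: int = 2048

    def validate(self) -> None:
        if self.kind not in ("ecfp", "physchem", "none"):
            raise InputError(f"unknown featurizer kind {self.kind!r}")
        if self.kind == "ecfp" and (self.radius < 1 or self.n_bits < 8):
            raise InputError("ecfp requires radius >= 1 and n_bits >= 8")


def _require_rdkit():
    try:
        from rdkit import Chem  # noqa: F401

        return Chem
    except ImportError as exc:
        raise CapabilityError(
            "molecular featurization needs RDKit; install the chemistry extra "
            "(pip install 'hvlforest[chem]') or provide numeric features directly"
        ) from exc


def featurize(
    table: pd.DataFrame,
    spec: FeaturizerSpec,
    smiles_col: str = "smiles",
) -> pd.DataFrame:
    """Turn a SMILES table into a numeric feature matrix (rows align with input).

    ``kind="none"`` passes the numeric columns through untouched, so a
    pre-featurized CSV flows down the same path. For the chemistry
    kinds, the index of the returned frame identifies the surviving
    input rows; unparseable SMILES are dropped and counted in the log.
    """
    spec.validate()
    if spec.kind == "none":
        numeric = table.select_dtypes(include=[np.number])
        if numeric.shape[1] == 0:
            raise InputError("no numeric feature columns found")
        return numeric.copy()

    Chem = _require_rdkit()
    if smiles_col not in table.columns:
        raise InputError(f"column {smiles_col!r} not found")
    mols, kept = [], []
    for idx, smi in table[smiles_col].items():
        mol = Chem.MolFromSmiles(str(smi))
        if mol is None:
            continue
        # round-trip through the canonical SMILES so equal structures
        # yield identical feature rows regardless of input writing
        mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
        mols.append(mol)
        kept.append(idx)
    n_bad = len(table) - len(mols)
    if n_bad:
        logger.warning("dropped %d unparseable SMILES of %d", n_bad, len(table))
    if not mols:
        raise InputError("no parseable SMILES in input")

    if spec.kind == "ecfp":
        from rdkit.Chem import rdFingerprintGenerator

        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=spec.radius, fpSize=spec.n_bits
        )
        mat = np.array([gen.GetFingerprintAsNumPy(m) for m in mols], dtype=np.uint8)
        cols = [f"bit{j}" for j in range(spec.n_bits)]
        return pd.DataFrame(mat, index=kept, columns=cols)

    from rdkit.Chem import Descriptors

    rows = [Descriptors.CalcMolDescriptors(m) for m in mols]
    frame = pd.DataFrame(rows, index=kept)
    return frame.astype(float)
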