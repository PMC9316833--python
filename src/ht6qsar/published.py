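"""The published six-descriptor binding-affinity model as a fixed predictor.

The model is a multilinear regression on the six descriptors computed by
:mod:`ht6qsar.descriptors`, with frozen printed coefficients (pKi, molar
scale):

    pKi = 6.754 - 0.109*com_Hhyd_3A - 0.700*ringC_S_4Bc
          - 0.604*flipo&S_ringN3B - 0.528*KRFPC620
          - 0.339*sp3N_sp2O_8B + 0.545*fsp3Cdon1B

Coefficient signs carry the pharmacophoric reading: fewer non-polar
hydrogens near the centre of mass, more negative ring-carbon charge near
sulfur, lipophilic shielding of ring nitrogens, avoiding triethylated
nitrogens and sp3-N/sp2-O pairings all raise predicted affinity, while a
donor on an sp3 carbon raises it directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType

import numpy as np
import pandas as pd

from .chem import MoleculeRecord
from .descriptors import MODEL1_DESCRIPTORS, compute_descriptors

_COEFFICIENTS = MappingProxyType({
    "com_Hhyd_3A": -0.109,
    "ringC_S_4Bc": -0.700,
    "flipo&S_ringN3B": -0.604,
    "KRFPC620": -0.528,
    "sp3N_sp2O_8B": -0.339,
    "fsp3Cdon1B": 0.545,
})

_STD_ERRORS = MappingProxyType({
    "intercept": 0.091,
    "com_Hhyd_3A": 0.014,
    "ringC_S_4Bc": 0.043,
    "flipo&S_ringN3B": 0.104,
    "KRFPC620": 0.075,
    "sp3N_sp2O_8B": 0.053,
    "fsp3Cdon1B": 0.067,
})


@dataclass(frozen=True)
class Model1:
    """Immutable published model; descriptor order is fixed."""

    intercept: float = 6.754
    coefficients: MappingProxyType = field(default_factory=lambda: _COEFFICIENTS)
    std_errors: MappingProxyType = field(default_factory=lambda: _STD_ERRORS)
    descriptor_names: tuple[str, ...] = MODEL1_DESCRIPTORS

    def predict(self, descriptors) -> float | np.ndarray:
        """Predicted pKi for a 6-vector (fixed order), mapping or table."""
        if isinstance(descriptors, dict):
            descriptors = [descriptors[n] for n in self.descriptor_names]
        elif isinstance(descriptors, pd.DataFrame):
            values = descriptors.loc[:, list(self.descriptor_names)].to_numpy(float)
            return self.intercept + values @ self._beta()
        values = np.asarray(descriptors, dtype=float)
        if values.shape[-1] != len(self.descriptor_names):
            raise ValueError(
                f"expected {len(self.descriptor_names)} descriptor values, "
                f"got {values.shape[-1]}")
        result = self.intercept + values @ self._beta()
        return float(result) if result.ndim == 0 else result

    def _beta(self) -> np.ndarray:
        return np.array([self.coefficients[n] for n in self.descriptor_names])


MODEL1 = Model1()


def model1_predict(descriptors) -> float | np.ndarray:
    """Module-level convenience around :meth:`Model1.predict`."""
    return MODEL1.predict(descriptors)


def predict_table(table: pd.DataFrame, ndigits: int = 3) -> pd.DataFrame:
    """Predictions for a descriptor table, rounded to the printed precision."""
    out = table.copy()
    out["predicted_pki"] = np.round(MODEL1.predict(table), ndigits)
    return out


def descriptor_contrast(mol_a: MoleculeRecord, mol_b: MoleculeRecord) -> pd.DataFrame:
    """Pairwise interpretation report: per-descriptor values, differences and
    the contribution of each difference to the predicted-pKi difference.

    The final row carries the totals; because the model is linear the
    prediction difference is exactly the sum of the per-descriptor
    contributions (the intercept cancels).
    """
    da = compute_descriptors(mol_a)
    db = compute_descriptors(mol_b)
    rows = []
    for name in MODEL1_DESCRIPTORS:
        delta = da[name] - db[name]
        rows.append({
            "descriptor": name,
            mol_a.mol_id or "A": da[name],
            mol_b.mol_id or "B": db[name],
            "delta": delta,
            "delta_predicted_pki": MODEL1.coefficients[name] * delta,
        })
    total = {
        "descriptor": "predicted_pki",
        mol_a.mol_id or "A": MODEL1.predict(da),
        mol_b.mol_id or "B": MODEL1.predict(db),
        "delta": MODEL1.predict(da) - MODEL1.predict(db),
        "delta_predicted_pki": MODEL1.predict(da) - MODEL1.predict(db),
    }
    return pd.DataFrame(rows + [total])
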