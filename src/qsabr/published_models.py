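"""The two published QSABR barrier equations as ready-to-use predictors.

Both models regress the Diels-Alder activation free energy (kcal/mol) on
frontier-orbital descriptors of the separated reactants.  The first was
fitted on all 72 reactions of the original study; the second on its
55-reaction training split and externally validated on the remaining 17.
Coefficients are frozen at their printed precision and are not refittable:
the descriptor values behind the original fits were never tabulated, so
these serve purely as predictors.

A caveat carried in the docs: the unit system of the original descriptor
matrix is not stated in the source; orbital-derived descriptors here are
assumed to be in atomic units (hartree) and dipoles in Debye, consistent
with the printed coefficient magnitudes, but predictions on user data are
not guaranteed to be commensurate with the original kcal/mol barriers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .descriptors import DescriptorVector
from .regression import LinearModel

_EQ6_TERMS = (
    # (name, coefficient, standard error)
    ("d_sof", 12.67, 3.4),
    ("omega_d", 1846.00, 748.0),
    ("d_homo", -148.00, 45.0),
    ("lumo_d", 291.00, 73.0),
    ("omega_a", 145.00, 54.0),
    ("chi_d", -485.00, 252.0),
)

_EQ10_TERMS = (
    ("d_lumo", -195.00, 49.0),
    ("omega_a", 1286.0, 333.0),
    ("d_omega", 1127.00, 326.0),
    ("lumo_d", 493.00, 147.0),
    ("delta_e", -6.10, 2.5),
    ("sof_d", 7.10, 3.9),
    ("dm_a", 0.21, 0.14),
)


@dataclass(frozen=True)
class PublishedModel:
    """A frozen barrier equation plus its reported validation statistics."""

    tag: str
    model: LinearModel

    @property
    def names(self):
        return self.model.names

    def predict(self, data) -> np.ndarray:
        return predict_barrier(self, data)


def eq6_model() -> PublishedModel:
    """Barrier equation fitted on the full 72-reaction set.

    Six descriptor terms; reported N=72, R2=0.831, F=53, Q2_loo=0.784,
    PRESS=437.271, SE=2.30 kcal/mol.
    """
    lm = LinearModel(
        intercept=-6.4,
        intercept_se=8.5,
        names=tuple(t[0] for t in _EQ6_TERMS),
        coef={t[0]: t[1] for t in _EQ6_TERMS},
        coef_se={t[0]: t[2] for t in _EQ6_TERMS},
        n_obs=72,
        r2=0.831,
        f_stat=53.0,
        se_reg=2.30,
        press=437.271,
        q2_loo=0.784,
        r2_pred=None,
        y_train_mean=None,
    )
    return PublishedModel(tag="eq6_all_data", model=lm)


def eq10_model() -> PublishedModel:
    """Barrier equation fitted on the 55-reaction training split.

    Seven descriptor terms; reported N=55, R2=0.865, F=43, Q2_loo=0.800,
    PRESS=300.461, SE=2.06 kcal/mol, external R2_pred=0.880 on 17 test
    reactions.
    """
    lm = LinearModel(
        intercept=-121.3,
        intercept_se=43.7,
        names=tuple(t[0] for t in _EQ10_TERMS),
        coef={t[0]: t[1] for t in _EQ10_TERMS},
        coef_se={t[0]: t[2] for t in _EQ10_TERMS},
        n_obs=55,
        r2=0.865,
        f_stat=43.0,
        se_reg=2.06,
        press=300.461,
        q2_loo=0.800,
        r2_pred=0.880,
        y_train_mean=None,
    )
    return PublishedModel(tag="eq10_training", model=lm)


def get_model(name: str) -> PublishedModel:
    """Look a bundled model up by tag (``eq6`` or ``eq10``)."""
    key = name.lower()
    if key in ("eq6", "eq6_all_data"):
        return eq6_model()
    if key in ("eq10", "eq10_training"):
        return eq10_model()
    raise KeyError(f"unknown published model {name!r} (eq6 or eq10)")


def predict_barrier(
    model: Union[PublishedModel, LinearModel],
    dv: Union[DescriptorVector, dict, pd.DataFrame],
) -> Union[float, np.ndarray]:
    """Predicted activation barrier: intercept + sum coef * descriptor.

    Accepts a single :class:`DescriptorVector` (returns a scalar), a
    name -> value mapping, or a descriptor DataFrame (returns an array).
    Raises ``KeyError`` naming any descriptor the model needs but the
    input lacks.
    """
    lm = model.model if isinstance(model, PublishedModel) else model
    if isinstance(dv, DescriptorVector):
        return float(lm.predict(dv.as_dict())[0])
    if isinstance(dv, dict):
        return float(lm.predict(dv)[0])
    return lm.predict(dv)
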