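"""Parameter container for the LPS → TNF-α → {IL-6, iNOS → NO} turnover cascade.

All structural constants of the cascade model live here: the zero-order
LPS-driven TNF-α production and its first-order loss, the delayed TNF-α-driven
turnover of IL-6 and iNOS, the iNOS^delta-driven NO production, the log-linear
baicalein inhibition coefficient, and the four baselines.
"""

from __future__ import annotations

import math

from pydantic import BaseModel, ConfigDict, Field, model_validator


class PDParameters(BaseModel):
    """Structural parameters of the inflammatory turnover cascade.

    Units are nominal: TNF-α and IL-6 are carried in pg/mL-equivalents, NO in
    μM-equivalents, iNOS as a dimensionless expression ratio normalized to its
    own time-0 value.  ``k_in_tnf`` multiplies nothing (zero-order production)
    so its unit is concentration·h⁻¹ even though it is conventionally printed
    as h⁻¹.

    Attributes
    ----------
    alpha
        Log-linear inhibition coefficient of baicalein on TNF-α production
        (dimensionless); the inhibition fraction is ``alpha * ln(C)`` for a
        baicalein concentration C in μM.
    k_in_tnf
        Zero-order TNF-α production constant under LPS (conc·h⁻¹).
    k_out_tnf
        First-order TNF-α elimination constant (h⁻¹).
    k_in_il6, k_out_il6, tau1
        IL-6 turnover: production driven by TNF-α delayed by ``tau1`` hours,
        first-order elimination.
    k_in_inos, k_out_inos, tau2
        iNOS turnover: production driven by TNF-α delayed by ``tau2`` hours.
        ``k_out_inos`` is conventionally fixed to 0 (expression plateaus).
    k_in_no, k_out_no, delta
        NO turnover: production proportional to iNOS**delta. ``k_out_no`` is
        conventionally fixed to 0.
    tnf0, il6_0, inos0, no0
        Baselines at t = 0 (the unstimulated control values); ``inos0`` is 1
        by construction of the relative expression ratio.
    """

    model_config = ConfigDict(frozen=True)

    alpha: float = Field(ge=0.0)
    k_in_tnf: float = Field(ge=0.0)
    k_out_tnf: float = Field(ge=0.0)
    k_in_il6: float = Field(ge=0.0)
    k_out_il6: float = Field(ge=0.0)
    tau1: float = Field(ge=0.0)
    k_in_inos: float = Field(ge=0.0)
    k_out_inos: float = Field(default=0.0, ge=0.0)
    tau2: float = Field(ge=0.0)
    k_in_no: float = Field(ge=0.0)
    k_out_no: float = Field(default=0.0, ge=0.0)
    delta: float = Field(gt=0.0)
    tnf0: float = Field(default=100.0, ge=0.0)
    il6_0: float = Field(default=50.0, ge=0.0)
    inos0: float = Field(default=1.0, ge=0.0)
    no0: float = Field(default=1.0, ge=0.0)

    @model_validator(mode="after")
    def _finite(self) -> "PDParameters":
        for name, value in self.__dict__.items():
            if not math.isfinite(value):
                raise ValueError(f"parameter {name!r} must be finite, got {value}")
        return self

    def check_arms(self, concentrations) -> None:
        """Raise if any arm concentration drives the inhibition fraction to ≥ 1.

        ``alpha * ln(C) >= 1`` would predict negative TNF-α production, which
        the log-linear effect model cannot represent.
        """
        for conc in concentrations:
            if conc > 1.0 and self.alpha * math.log(conc) >= 1.0:
                raise ValueError(
                    f"alpha*ln(C) = {self.alpha * math.log(conc):.4g} >= 1 at "
                    f"C = {conc} μM: total production shutdown is outside the model"
                )

    def replace(self, **updates) -> "PDParameters":
        """Return a copy with the given fields replaced."""
        return self.model_copy(update=updates)


#: Structural parameter names in canonical order (baselines last).
PARAM_NAMES: tuple[str, ...] = (
    "alpha",
    "k_in_tnf",
    "k_out_tnf",
    "k_in_il6",
    "k_out_il6",
    "tau1",
    "k_in_inos",
    "k_out_inos",
    "tau2",
    "k_in_no",
    "k_out_no",
    "delta",
    "tnf0",
    "il6_0",
    "inos0",
    "no0",
)


def baicalein_reference_params() -> PDParameters:
    """Reference estimates for baicalein inhibition of the LPS-stimulated
    cascade in RAW264.7 macrophages, with nominal baselines.

    These are the population estimates reported for this model fitted to
    RAW264.7 time-course data (TNF-α/IL-6 by ELISA, iNOS by immunoblot ratio,
    NO by Griess), with the iNOS and NO elimination constants fixed to zero.
    Baselines are nominal conventions: tnf0 = 100, il6_0 = 50, inos0 = 1,
    no0 = 1.
    """
    return PDParameters(
        alpha=0.0832,
        k_in_tnf=3.74e3,
        k_out_tnf=0.0463,
        k_in_il6=0.353,
        k_out_il6=0.143,
        tau1=1.38,
        k_in_inos=0.00169,
        k_out_inos=0.0,
        tau2=1.41,
        k_in_no=0.0605,
        k_out_no=0.0,
        delta=1.35,
        tnf0=100.0,
        il6_0=50.0,
        inos0=1.0,
        no0=1.0,
    )
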