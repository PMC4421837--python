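"""Reference rate-constant sets for K18 tau and its FTDP-17 variants.

The heparin-induced aggregation of the K18 repeat-domain construct
(10 μM, 37 °C, pH 7.0 ammonium acetate) is characterized by a handful of
robust observations: roughly half the protein remains soluble at
completion, oligomers number about 0.1% of soluble species (a peak number
concentration near 5 nM), and fibril formation is ~90% complete within
3 h.  The K18 constants below were calibrated once against exactly those
observations under the standard model configuration (x_a = 3, f_a = 2000,
n_c = 2); they are representative values, not a fit to any particular raw
data set.

Variant constants are derived from K18 by applying the reported
mutation-induced activation-free-energy changes for each process,
k_mut = k_wt·exp(−ΔΔG‡/RT):

=========  =====  ======  ======  =====
construct  k_n    ǩ_n     k_+     k_off
=========  =====  ======  ======  =====
ΔK280      −4.9   −1.5    +2.5    +1.7
P301L      −2.7   −1.8    +3.1    +4.6
PP         +4.1   ND      ND      ND
=========  =====  ======  ======  =====

(RT units; negative = faster in the variant; ND = not determined.)
For the anti-aggregant PP mutant only the nucleation change is known, so
only ``k_n`` is meaningful in ``K18_PP`` — the remaining entries are
inherited from K18 as placeholders and flagged in ``PP_UNDETERMINED``.
"""

from __future__ import annotations

import math

from .conversion_model import ModelConfig, RateConstants

#: Calibrated wild-type K18 constants (μM, h units; n_c = 2).
K18 = RateConstants(
    k_n=6.9658e-05,  # μM⁻¹·h⁻¹
    k_n_rev=0.43536,  # h⁻¹
    k_plus=0.038830,  # μM⁻¹·h⁻¹
    k_off=0.31139,  # h⁻¹
    n_c=2,
)

#: Reported ΔΔG‡ (RT units) per process, variant minus wild type.
DDG_RT = {
    "dK280": {"k_n": -4.9, "k_n_rev": -1.5, "k_plus": 2.5, "k_off": 1.7},
    "P301L": {"k_n": -2.7, "k_n_rev": -1.8, "k_plus": 3.1, "k_off": 4.6},
    "PP": {"k_n": 4.1},
}

#: Reported standard errors on the ΔΔG‡ values (RT units).
DDG_SE_RT = {
    "dK280": {"k_n": 0.7, "k_n_rev": 0.7, "k_plus": 0.6, "k_off": 1.0},
    "P301L": {"k_n": 0.7, "k_n_rev": 0.7, "k_plus": 0.8, "k_off": 1.1},
    "PP": {"k_n": 0.7},
}

PP_UNDETERMINED = ("k_n_rev", "k_plus", "k_off")


def variant(base: RateConstants, ddg_rt: dict[str, float]) -> RateConstants:
    """Apply per-process ΔΔG‡ values (RT) to a base parameter set."""
    kwargs = {
        name: getattr(base, name) * math.exp(-ddg_rt.get(name, 0.0))
        for name in ("k_n", "k_n_rev", "k_plus", "k_off")
    }
    return RateConstants(n_c=base.n_c, **kwargs)


K18_DK280 = variant(K18, DDG_RT["dK280"])
K18_P301L = variant(K18, DDG_RT["P301L"])
K18_PP = variant(K18, DDG_RT["PP"])

#: Standard in-vitro configuration: 10 μM monomer, trimeric oligomers,
#: ~1 μm fibrils.
IN_VITRO = ModelConfig(x_a=3.0, f_a=2000.0, m0=10.0)

#: Intracellular configuration: 2 μM tau in a neuronal cell.
INTRACELLULAR = ModelConfig(x_a=3.0, f_a=2000.0, m0=2.0)

#: Typical neuronal cell volume, litres (6,000 μm³).
CELL_VOLUME_L = 6e-12

CONSTRUCTS = {
    "K18": K18,
    "dK280": K18_DK280,
    "P301L": K18_P301L,
    "PP": K18_PP,
}
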