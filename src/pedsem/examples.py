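"""Ready-made model descriptions for common genetic SEM analyses.

Each function returns model-description text (see :mod:`pedsem.model`)
for one of the canonical analysis types: genetic association with a
latent trait, variance-component linkage with a latent trait, a
multi-level SEM with polygenic effects, and a pleiotropy CFA in which one
genetic factor drives two latent traits.
"""

from __future__ import annotations

__all__ = [
    "association_model",
    "linkage_model",
    "multilevel_model",
    "pleiotropy_model",
    "ALL_EXAMPLES",
]


def association_model(snp: str = "rs6040343") -> str:
    """Latent trait measured by three indicators, regressed on a SNP.

    The latent variable carries polygenic and environmental variance
    components; each indicator has its own environmental residual.
    """
    return f"""
L1 =~ P1 + P2 + P3
L1 ~ {snp} + <p,e>
P1 ~ <e>
P2 ~ <e>
P3 ~ <e>
"""


def linkage_model(marker: str = "rs6040356") -> str:
    """Latent trait with a marker-specific linkage variance component.

    IBD sharing at ``marker`` drives the genetic component 'a'; a random
    environmental component completes the latent covariance.  Add ``p``
    to the component group for a polygenic background.
    """
    return f"""
L1 =~ P1 + P2 + P3
L1 ~ <a({marker}),e>
P1 ~ <e>
P2 ~ <e>
P3 ~ <e>
"""


def multilevel_model(snp: str = "rs6040343") -> str:
    """Multi-level SEM: anger -> stress -> blood pressure, SNP on stress.

    Three latent variables, each measured by two indicators; every trait
    and latent variable has its own polygenic and environmental
    components except stress, whose variances are fixed at 0.1.
    """
    return f"""
anger =~ A1 + A2
bp =~ SBP + DBP
stress =~ S1 + S2
bp ~ anger + stress + <p,e>
stress ~ anger + {snp} + <p,e>
anger ~ <p,e>
A1 ~ <p,e>
A2 ~ <p,e>
SBP ~ <p,e>
DBP ~ <p,e>
S1 ~ <p,e>
S2 ~ <p,e>
var(stress, p) = 0.1
var(stress, e) = 0.1
"""


def pleiotropy_model(snp: str = "rs6040343") -> str:
    """CFA with a pleiotropic genetic factor influenced by a SNP.

    Two latent traits with three indicators each; a shared genetic factor
    g1 (anchored by fixing its coefficient to z1 at 1) transmits the SNP
    effect to both.
    """
    return f"""
z1 =~ X1 + X2 + X3
z2 =~ X4 + X5 + X6
z1 ~ g1 + <p,e>
z2 ~ g1 + <p,e>
g1 ~ {snp} + <p,e>
X1 ~ <e>
X2 ~ <e>
X3 ~ <e>
X4 ~ <e>
X5 ~ <e>
X6 ~ <e>
coef(g1, z1) = 1
"""


ALL_EXAMPLES = {
    "association": association_model,
    "linkage": linkage_model,
    "multilevel": multilevel_model,
    "pleiotropy": pleiotropy_model,
}
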