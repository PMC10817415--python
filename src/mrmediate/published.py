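"""Published effect sizes used as worked-example inputs.

The DKK1 -> PDGF-B -> AMI mediation analysis reports, on the log-odds /
standardized scale: a total DKK1->AMI effect of 0.00208, a DKK1->PDGF-B
effect (beta1) of 0.32490 and a PDGF-B->AMI effect (beta2) of 0.00358,
each with its 95% CI. These printed values are the inputs to the mediation
arithmetic reproduced by the worked example and the acceptance script;
standard errors are back-derived from the CIs via (upper-lower)/(2*1.96).
"""

from __future__ import annotations

from .estimators import MREstimate

Z95 = 1.96  # the printed CIs round on a 1.96 z


def _estimate(name: str, beta: float, ci: tuple[float, float],
              n_snps: int) -> MREstimate:
    se = (ci[1] - ci[0]) / (2.0 * Z95)
    est = MREstimate(method=name, beta=beta, se=se, ci_low=ci[0],
                     ci_high=ci[1], pvalue=float("nan"), n_snps=n_snps)
    return est


#: DKK1 -> AMI (total effect), 3 instruments
TOTAL_DKK1_AMI = _estimate("ivw", 0.00208, (0.00056, 0.00360), 3)
#: DKK1 -> PDGF-B (beta1), 3 instruments
BETA1_DKK1_PDGFB = _estimate("ivw", 0.32490, (0.06828, 0.58152), 3)
#: PDGF-B -> AMI (beta2), 7 instruments
BETA2_PDGFB_AMI = _estimate("ivw", 0.00358, (0.00136, 0.00579), 7)

#: instruments reported for each exposure trait
DKK1_INSTRUMENTS = ("rs1194673", "rs6993770", "rs7080386")
PDGFB_INSTRUMENTS = ("rs10761741", "rs10876550", "rs11594179", "rs11639051",
                     "rs11770907", "rs4541868", "rs68066031")
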