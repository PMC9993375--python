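"""Health-state labels shared by the decision tree and the Markov cohort model.

The long-term model distinguishes five states: medically-maintained remission,
a within-cycle surgery (colectomy) event, post-surgical complications,
surgical remission, and death (absorbing).
"""

REMISSION_MED = "remission_med"
SURGERY = "surgery"
COMPLICATIONS = "complications"
SURG_REMISSION = "surgical_remission"
DEAD = "dead"

#: Canonical column order for cohort traces and transition matrices.
STATES = (REMISSION_MED, SURGERY, COMPLICATIONS, SURG_REMISSION, DEAD)

#: States that carry annual utility/cost payoffs (SURGERY is a transient
#: within-cycle event and accrues only one-off payoffs).
PAYOFF_STATES = (REMISSION_MED, COMPLICATIONS, SURG_REMISSION, DEAD)

STATE_INDEX = {s: i for i, s in enumerate(STATES)}

#: EQ-5D-3L UK tariff bounds for utility weights.
UTILITY_MIN = -0.594
UTILITY_MAX = 1.0
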