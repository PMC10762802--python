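"""Sequential Bayes Factor design: add participants until BF > 3.

Starts at 10 participants per group and adds batches of 5 until the Bayes
factor for the group effect (group-only model vs subject-only null) crosses
3 in either direction, or 20 per group is reached.
"""

from gazeshift import sequential_design
from gazeshift.synthetic_data import participant_stream

G = frozenset({"group"})
stream = participant_stream(seed=4)  # no true group difference
decision = sequential_design(stream, n_initial=10, batch=5, threshold=3.0,
                             n_max=20, seed=0)

for i, (n, res) in enumerate(decision.rounds, start=1):
    bf10 = res.bf10_by_model[G]
    bf01 = 1.0 / bf10
    print(f"round {i}: n = {n}/group  BF10 = {bf10:.3f}  BF01 = {bf01:.3f}")
if decision.stopped:
    print(f"stopped at round {decision.stop_round}: evidence threshold "
          f"{decision.threshold} crossed")
else:
    print("maximum sample reached without crossing the threshold")
# Under a null group effect BF01 grows with n, so sampling typically stops
# after one or two rounds in favor of the null.
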