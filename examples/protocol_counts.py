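"""Build the standard LED protocol and count the analysed gaze shifts.

The 53-light sequence defines 52 target-to-target gaze shifts; only the
large 75/80-degree shifts enter the analysis.
"""

from gazeshift import build_standard_protocol, count_large_shifts, shift_amplitudes

protocol = build_standard_protocol(seed=0)
amplitudes = shift_amplitudes(protocol)

print(f"target lights:        {len(protocol.targets)}")
print(f"gaze shifts:          {len(amplitudes)}")
print(f"large (75/80) shifts: {count_large_shifts(amplitudes)}")
print(f"session duration:     {protocol.duration_s:.1f} s")
# 53 lights -> 52 shifts, of which 43 are the large ones analysed downstream.
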