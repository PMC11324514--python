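"""Client recruitment kinetics: Hill fits and arrival-time differences.

Generates three noisy enrichment-ratio traces with staggered half-times
(fast, intermediate and late clients of the junctional scaffold), fits
each with the Hill model and reports t_1/2 and the arrival delays.
"""

from prewetbelt.quantify import fit_hill
from prewetbelt.synth import generate_kinetics

t, traces, truth = generate_kinetics([5.0, 18.0, 35.0], seed=1)

fits = [fit_hill(t, y) for y in traces]
print("client   programmed t_1/2 (min)   fitted t_1/2 (min)   Hill n")
for i, (fit, rec) in enumerate(zip(fits, truth.records)):
    print(f"{i:6d}   {rec['t_half']:22.1f}   {fit.t_half:18.2f}   {fit.n:6.2f}")

first = fits[0]
print("\narrival delays relative to the fastest client:")
for i, fit in enumerate(fits[1:], start=1):
    print(f"  client {i}: {fit.t_half - first.t_half:+.2f} min")
print()
print("The arrival-time difference of two proteins is the difference of")
print("their fitted half-times; the rank order (fast < intermediate < late)")
print("is preserved at the default noise level.")
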