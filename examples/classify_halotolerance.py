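"""Halotolerance classification from stated salt ranges.

Classifies a few literature-style strain descriptions under the
Kushner/Ventosa scheme and shows the percent <-> molar conversion the
thresholds rely on.
"""

from halocharge import SaltRange, classify, percent_to_molar

strains = {
    "requires 21% salt": SaltRange(required_min=21.0, optimal_low=21.0, optimal_high=25.0),
    "grows 5-30%, broad range": SaltRange(
        optimal_low=5.0, optimal_high=10.0, tolerated_max=30.0, grows_at_low_salt=True
    ),
    "optimal 3.5-14% (0.6-2.4 M)": SaltRange(optimal_low=3.5, optimal_high=14.0),
    "grows 0-10% from fresh water": SaltRange(tolerated_max=10.0, grows_at_low_salt=True),
    "confined below 2%": SaltRange(
        optimal_low=0.0, optimal_high=1.0, tolerated_max=2.0, grows_at_low_salt=True
    ),
}

print("Class boundaries: extreme halophile requires >= 2 M; extremely")
print("halotolerant grows from low salt beyond 2.5 M; moderate halophiles")
print("grow optimally inside 0.5-2.5 M.\n")
for label, salt in strains.items():
    print(f"  {label:32s} -> {classify(salt).value}")

print("\nPercent w/v to molar (M = pct * 10 / 58.44):")
for pct in (2.9, 5.844, 14.61, 21.0):
    print(f"  {pct:6.3f}% = {percent_to_molar(pct):.3f} M")
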