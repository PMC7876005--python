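"""Peak deconvolution, mass calibration and oligomeric-state calls.

Builds a two-peak elution profile for a 33 kDa protein that elutes as two
larger assemblies, splits it into single Gaussian peaks, assigns each an
apparent mass via a log-linear reference-protein calibration, and applies
the 1.5 oligomeric-ratio rule.
"""

import numpy as np

import cofrac_pmi as cp
from cofrac_pmi.profiles import gaussian

# log-linear calibration: ~5.2 MDa at fraction 1 down to 20 kDa at fraction 38
refs = cp.generate_calibration_refs(5)
curve = cp.fit_calibration(refs)
print(f"calibration: log10(mass) = {curve.slope:.4f} * fraction + {curve.intercept:.3f} "
      f"(R^2 = {curve.r_squared:.4f})")

monomer_da = 33e3
x = np.arange(1, 49, dtype=float)
# the protein elutes as a large assembly (~270 kDa) and a dimer (~66 kDa)
profile = gaussian(x, 1.0, curve.fraction_of(270e3), 1.5) + gaussian(
    x, 0.6, curve.fraction_of(66e3), 1.5
)
peaks = cp.deconvolve(cp.normalize_profile(profile, "enzyme", "protein"))
print(f"\ndeconvolved {len(peaks)} peaks from the profile:")
for peak in peaks:
    peak = cp.apparent_mass(peak, curve)
    call = cp.classify_oligomeric("enzyme", peak, monomer_da)
    state = "multimeric" if call.multimeric else "monomeric"
    print(
        f"  peak {peak.ordinal}: centre fraction {peak.center:5.2f}, "
        f"apparent mass {peak.apparent_mass / 1e3:6.1f} kDa, "
        f"oligomeric ratio {call.ratio:.2f} -> {state}"
    )
print(
    "\nBoth peaks sit well above the 33 kDa monomer (ratio > 1.5), so the "
    "enzyme elutes exclusively in multimeric assemblies."
)
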