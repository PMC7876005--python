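"""End-to-end synthetic benchmark: planted interactions through the full SEC arm.

Generates the standard ground-truthed co-fractionation dataset (200 proteins,
30 metabolites, 20 planted protein-metabolite interactions, 3 replicates at
15% CV), runs deconvolution -> calibration -> co-elution scoring -> ROC/FDR ->
network, and scores the calls against the planted truth.
"""

import json

import cofrac_pmi as cp

report = cp.run_demo(seed=1)
print(json.dumps(report.to_dict(), indent=2, sort_keys=True))
print()
print(
    f"Of {report.n_planted} planted interactions the network recovered "
    f"{report.n_recovered} (sensitivity {report.sensitivity:.0%}) at PCC >= 0.7."
)
print(
    f"{report.n_artifact_edges} extra edges are co-elution artifacts: proteins whose "
    "peaks genuinely overlap the planted target's peak, which co-fractionation "
    "cannot distinguish; the method relies on orthogonal evidence to resolve them."
)
print(
    f"The null-based FDR estimate at the operating point is {report.estimated_fdr:.1%}; "
    f"{report.n_false_edges} called edges were outright false (realized FDR "
    f"{report.realized_fdr:.1%} among resolvable calls)."
)
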