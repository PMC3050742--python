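"""Predict interaction points for held-out compounds and compare to random.

Runs the full protocol on the default fingerprint-space synthetic library
(the class frequencies of the curated NF-κB set): 5 random train/test
splits x 5 clustering seeds, nearest cluster by medoid similarity, label
transfer at the 66.6% predominance level for clusters with at least two
labelled members, versus assigning clusters at random.
"""

import warnings

import numpy as np

from moaclust import (
    DescriptorSet,
    ProtocolConfig,
    SearchMethod,
    SyntheticConfig,
    generate_fp_library,
    run_protocol,
)

records, vectors = generate_fp_library(SyntheticConfig(noise_rate=0.05, rng_seed=42))
print(f"library: {len(records)} compounds "
      f"({sum(1 for r in records if r.labels)} labelled)")

cfg = ProtocolConfig(
    descriptor_sets=(DescriptorSet.ECFP4,),
    methods=(SearchMethod.CLUSTER_CENTRE,),
    levels=(2 / 3,),
    min_sizes=(2,),
    thresholds=(None, 0.7),
    include_unknown_modes=(False,),
    baseline_reps=25,
    rng_seed=7,
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    bundle = run_protocol(records, cfg, vectors_by_set={DescriptorSet.ECFP4: vectors})

m = bundle.metrics
for thr, label in ((None, "no similarity threshold"), (0.7, "similarity >= 0.7")):
    sel = m[m.threshold.isna()] if thr is None else m[m.threshold == 0.7]
    print(
        f"\n{label} (mean over {len(sel)} runs):"
        f"\n  % of all queries correct:        {sel.pct_correct_all.mean():5.1f}"
        f" (sd {sel.pct_correct_all.std():.1f})"
        f"\n  % of made predictions correct:   {sel.pct_correct_predicted.mean():5.1f}"
        f"\n  queries predicted (of 60):       {sel.n_predicted.mean():5.1f}"
        f"\n  random-assignment baseline (%):  {sel.baseline_analytic_pct.mean():5.1f}"
    )

print(
    "\nPredictions that are made are essentially always correct (the nearest"
    "\ncluster is a pure structural series); accuracy over all queries is bounded"
    "\nby coverage — queries abstain when the nearest cluster has no label"
    "\nreaching the 66.6% predominance level."
)
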