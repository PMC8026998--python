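"""Light-response pipeline on count-tier simulated MEA data.

Simulates control-like and treated-like retinal explants (200 electrodes
each, 6 flash intensities x 20 repetitions), classifies light-activated
electrodes (paired t, p < 0.01, t > 2, activated at >= 3 of 5 photopic
intensities), computes the response ratio and compares the groups per
intensity with a Wilcoxon rank-sum test.
"""

import numpy as np

from retinakit import mea, synth


def run_arm(label, on_rate, seed):
    protocol = synth.make_protocol()
    model = synth.RateModel.flat(protocol.intensities, on_rate=on_rate, spont_rate=5.0)
    counts = synth.simulate_trial_counts(protocol, model, n_channels=200, seed=seed)
    activation = mea.test_activation(counts)
    selection = mea.select_channels(activation, protocol)
    ratios = mea.response_ratio(counts, selection)
    included = int(selection["included"].sum())
    med = np.nanmedian(ratios[ratios["intensity"].isin(protocol.photopic)]["ratio"])
    print(f"{label:8s}: {included}/200 electrodes included, median response ratio {med:.3f}")
    return ratios


control = run_arm("control", on_rate=33.5, seed=1)
treated = run_arm("treated", on_rate=50.0, seed=2)

comparison = mea.compare_groups(control, treated)
print("\nper-intensity rank-sum comparison (control vs treated):")
for _, row in comparison.iterrows():
    print(
        f"  {row['intensity']:.2g} photons/cm2/s: medians "
        f"{row['median_control']:.3f} vs {row['median_treated']:.3f}, p = {row['p_value']:.2e}"
    )
print(
    "\nA response ratio of +1 means firing only during light; 0 means no change "
    "over spontaneous activity. Higher treated medians indicate stronger "
    "light-driven output of the treated retina."
)
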