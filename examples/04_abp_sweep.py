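"""A miniature actin-binding-protein sweep.

Varies the cofilin synthesis rate over two decades around the table value
and reports end-point membrane area and circularity (mean ± standard error
over a few replicate seeds, Bessel-corrected).  This is the reduced
version of the full three-protein sweep; see analysis.sweep for the
general interface.
"""

from spinedgg import RunConfig, analysis
from spinedgg.params import ModelParams

base = ModelParams().i_cof
cfg = RunConfig(t_end=0.15, sample_interval=0.15, seed=5)
table = analysis.sweep(cfg, "i_cof", [0.1 * base, base, 10 * base], reps=3,
                       observables=("area_um2", "circularity",
                                    "bound_cofilin"))
print(table[["value", "n", "area_um2_mean", "area_um2_se",
             "circularity_mean", "bound_cofilin_mean"]].to_string(index=False))
print("\nEach row: one cofilin synthesis rate (M/s); area/circularity are "
      "end-point means over the replicates; bound_cofilin counts cofilin "
      "molecules decorating the network at the end point.")
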