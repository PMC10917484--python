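"""Run the optimization ablation on a small phantom.

Each stage turns on one (or all) of the structural optimizations and is
timed and verified against the reference run.  Verdicts are computed from
byte comparisons and measured relative errors; the wall-clock column is
specific to the machine this runs on and is informational only.
"""

from hessdenoise import DenoiseParams, PhantomSpec, StageSpec, format_table, make_phantom, run_benchmark

_, noisy = make_phantom(PhantomSpec(shape=(32, 32, 16), seed=1))

stages = [StageSpec(s) for s in
          ("reference", "vectorized", "inlined", "dedup",
           "single_precision", "multicore")]
records = run_benchmark(noisy, stages, DenoiseParams(iterations=25))
print(format_table(records))
print("\nbit_identical: output bytes equal the reference output;")
print("within_tolerance: max relative error below 1e-4 (precision change only).")
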