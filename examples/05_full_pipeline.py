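"""Run the whole pipeline end to end and write every table plus a manifest.

Equivalent to `navdyn all --out <dir>`: simulate -> condition -> ICS/decoding
with permutation tests -> event regression -> ISFC -> group statistics.
All outputs are TSV; manifest.json records the config hash and seed so the
run is exactly reproducible.
"""

import tempfile
from pathlib import Path

from navdyn import CohortConfig, PipelineConfig, run_all

cfg = PipelineConfig(
    cohort=CohortConfig(n_young=8, n_old=8),
    seed=7,
    n_perm=300,
    run_seedwise=False,
)

out_dir = Path(tempfile.mkdtemp(prefix="navdyn_"))
result = run_all(cfg, out_dir)

print(f"outputs written to {out_dir}:")
for path in sorted((out_dir / "results").glob("*.tsv")):
    print("  ", path.name)

ics = result.tables["ics_summary"].nlargest(3, "mean_ics")
print("\ntop regions by mean ICS (with permutation p):")
print(ics[["label", "mean_ics", "p_perm", "p_fdr"]].to_string(index=False))

beh = result.tables["behavior_summary"].iloc[0]
print(f"\nage-performance correlation: r = {beh.age_performance_r:.2f} "
      f"(motion-partialled {beh.age_performance_r_motion_partialled:.2f})")
print("  -> spatial memory declines with age in the synthetic cohort, and")
print("     part of that decline is carried by medial-temporal coupling")
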