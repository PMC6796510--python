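"""Run the whole pipeline (simulate -> mark -> diff -> expr -> compare ->
profile -> enrich) from one config and inspect the manifest.
"""
from pathlib import Path

from k27pipe.pipeline import RunConfig, run
from k27pipe.synthetic_data import SimulationConfig

out = Path("scratch/example_run")
cfg = RunConfig(simulation=SimulationConfig(seed=1))
manifest = run(cfg, out)

print(f"pipeline wrote {len(manifest['outputs'])} files to {out}/")
for name in sorted(manifest["outputs"]):
    print(" ", name)
print("\nevery file is checksummed in manifest.json; rerunning with the same")
print("seed reproduces identical checksums.")
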