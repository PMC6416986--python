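"""One-command synthetic end-to-end run.

Simulates a full flight-vs-ground dataset (genome, gene models, six
methylome count tables, an expression matrix), writes it in the pipeline's
on-disk input formats, runs every stage, and prints the report.  Equivalent
to `dmrkit demo` on the command line.
"""

import json

from dmrkit.pipeline import demo

report = demo("demo_output", seed=0)
printable = {k: v for k, v in report.items() if not k.startswith("_")}
print(json.dumps(printable, indent=2, default=str))
print()
print("All stage outputs (DmC/DMR tables, bedGraph tracks, metagene "
      "profiles, DEG and integration tables, report.json) are under "
      "demo_output/results; truth_*.tsv under demo_output record what was "
      "planted.")
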