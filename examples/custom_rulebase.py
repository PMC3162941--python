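"""Edit the engine configuration: everything is one reviewable YAML file.

Saves the shipped default configuration, tightens the alert urgency of the
low-pressure rule from low to high, reloads, and shows the change take
effect — the workflow a clinical team would use to review and adapt the
rule base without touching code.
"""

import tempfile
from pathlib import Path

import yaml

from fuzzyvitals import build_engine, default_config, load_config, save_config

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "config.yaml"
    save_config(default_config(), path)

    raw = yaml.safe_load(path.read_text())
    rule2 = next(r for r in raw["rules"] if r["id"] == 2)
    print(f"rule 2 urgency before: {rule2['urgency']}")
    rule2["urgency"] = "high"
    path.write_text(yaml.safe_dump(raw, sort_keys=False))

    engine = build_engine(load_config(path))
    diag = engine.infer(33, 94)
    print(f"rule 2 urgency after:  {diag.urgency} "
          f"(label={diag.label}, score={diag.score:.2f})")

print("\nThe same low-pressure reading now raises a high-priority alert;")
print("validation would have rejected the edit had it referenced an")
print("undefined term or broken a membership function.")
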