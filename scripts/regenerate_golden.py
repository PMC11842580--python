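"""Regenerate the frozen golden-fixture expectations.

Run after an intentional behavior change:

    python scripts/regenerate_golden.py

Rewrites ``src/cdi/data/golden_expectations.json`` with the class
histograms of a fresh version-4 run (and a version-2 run for the
out-of-season fixture) of every registered golden fixture.
"""

from __future__ import annotations

import json
from pathlib import Path

from cdi.pipeline import PipelineParams, run_cdi
from cdi.synthetic import golden_fixture, run_summary

OUT = Path(__file__).resolve().parents[1] / "src" / "cdi" / "data" / "golden_expectations.json"


def main() -> None:
    expectations: dict[str, dict] = {}
    for name in ("nordic-snow", "france-offseason", "all-zero"):
        fx = golden_fixture(name)
        entry: dict[str, dict] = {}
        for version in (4, 2) if name == "france-offseason" else (4,):
            run = run_cdi(fx.scene, fx.first, fx.last, PipelineParams(version=version))
            entry[f"v{version}"] = run_summary(run.maps)
        expectations[name] = entry
        print(name, entry)
    OUT.write_text(json.dumps(expectations, indent=2) + "\n")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
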