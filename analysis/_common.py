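"""Shared paths for the analysis drivers."""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
CONFIG_PATH = ROOT / "analysis" / "study_config.yaml"
RESULTS = ROOT / "results" / "study"
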