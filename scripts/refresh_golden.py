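"""Regenerate the frozen golden-run hashes in tests/test_acceptance.py.

Run from the repository root after an intentional change to any output
format, then review the diff:

    python scripts/refresh_golden.py
"""

import hashlib
import re
import sys
import tempfile
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "tests"))

from conftest import GOLDEN_CONFIG  # noqa: E402

from cernet.pipeline import run_pipeline  # noqa: E402


def main() -> None:
    out = Path(tempfile.mkdtemp()) / "run"
    run_pipeline(GOLDEN_CONFIG, out)
    lines = ["GOLDEN_SHA256 = {"]
    for path in sorted(out.rglob("*")):
        if path.is_file():
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            lines.append(f'    "{path.relative_to(out)}":')
            lines.append(f'        "{digest}",')
    lines.append("}")
    target = ROOT / "tests" / "test_acceptance.py"
    text = target.read_text()
    text = re.sub(r"GOLDEN_SHA256 = \{.*?\n\}", "\n".join(lines), text, flags=re.S)
    target.write_text(text)
    print(f"refreshed {len(lines) // 2} hashes in {target}")


if __name__ == "__main__":
    main()
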