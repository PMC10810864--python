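"""Run configuration: a key: value file whose entries seed CLI defaults.

Example config file::

    # pipeline defaults
    calibrate.preset: test
    calibrate.seed: 7
    screen.hours: 24

Keys are ``<subcommand>.<option>``; explicit command-line flags always win.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    values: dict = field(default_factory=dict)

    def default_map(self) -> dict:
        """Nested mapping consumable as a click default_map."""
        out: dict = {}
        for key, value in self.values.items():
            if "." in key:
                cmd, opt = key.split(".", 1)
                out.setdefault(cmd, {})[opt.replace("-", "_")] = value
            else:
                out[key.replace("-", "_")] = value
        return out


def load_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file {path} does not exist")
    values = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key: value'")
        key, _, raw = line.partition(":")
        raw = raw.strip()
        for cast in (int, float):
            try:
                value = cast(raw)
                break
            except ValueError:
                continue
        else:
            value = raw
        values[key.strip()] = value
    return RunConfig(values)
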