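"""Registration run reports."""

from __future__ import annotations

import json
from dataclasses import dataclass, field


@dataclass
class RegistrationReport:
    """Outcome of a registration run.

    ``cost_trace`` holds the cost after every accepted step (level markers
    in ``level_breaks``); ``metrics`` may carry downstream evaluation numbers
    (mse, foe); ``extras`` holds solver diagnostics such as folding counts.
    """

    cost_trace: list = field(default_factory=list)
    level_breaks: list = field(default_factory=list)
    final_cost: float = float("nan")
    converged: bool = True
    warnings: list = field(default_factory=list)
    metrics: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "cost_trace": [float(c) for c in self.cost_trace],
            "level_breaks": list(self.level_breaks),
            "final_cost": float(self.final_cost),
            "converged": bool(self.converged),
            "warnings": list(self.warnings),
            "metrics": {k: float(v) for k, v in self.metrics.items()},
            "extras": self.extras,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text
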