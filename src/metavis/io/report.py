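from __future__ import annotations

from dataclasses import dataclass, field


class FormatError(ValueError):
    """Unreadable input: malformed XML, wrong language, bad header."""


@dataclass
class FormatReport:
    format: str  # xgmml | sbgnml_pd | kgml | cd_sbml | cobra_map | sbml_model
    warnings: list[str] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    def warn(self, message: str) -> None:
        self.warnings.append(message)
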