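"""Rule-based postprocessing for combination codes.

ICD-10 contains combination codes: single codes that capture what
would otherwise be coded as two or more separate diagnoses.  A
classifier trained per-label tends to predict the components (or the
wrong variant), so predicted code sets are repaired with user-defined
rules: a *combine* rule replaces a co-occurring component set with the
combination code, a *split* rule expands a combination code into its
components.  Rules are applied in a single pass, ordered by priority
then file order — no fixpoint iteration, so rule cycles cannot loop.

Rule file format, one rule per line (``#`` comments allowed)::

    combine A+B=C [@priority]
    split C=A+B [@priority]
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence


@dataclass(frozen=True)
class CombinationRule:
    kind: str  # "combine" | "split"
    pattern: frozenset[str]  # component set (combine) or single code (split)
    replacement: tuple[str, ...]
    priority: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("combine", "split"):
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if not self.pattern:
            raise ValueError("rule pattern must be nonempty")
        if not self.replacement:
            raise ValueError("rule replacement must be nonempty")
        if self.kind == "split" and len(self.pattern) != 1:
            raise ValueError("split rule pattern must be a single code")
        if self.pattern & set(self.replacement):
            raise ValueError("pattern and replacement must be disjoint")


def _parse_line(line: str, lineno: int) -> CombinationRule:
    body = line
    priority = 0
    if "@" in line:
        body, _, prio = line.rpartition("@")
        try:
            priority = int(prio.strip())
        except ValueError as exc:
            raise ValueError(f"line {lineno}: bad priority {prio!r}") from exc
    parts = body.split(None, 1)
    if len(parts) != 2 or "=" not in parts[1]:
        raise ValueError(f"line {lineno}: expected 'combine A+B=C' or 'split C=A+B'")
    kind, rest = parts[0].strip(), parts[1]
    lhs, _, rhs = rest.partition("=")
    pattern = frozenset(c.strip() for c in lhs.split("+") if c.strip())
    replacement = tuple(c.strip() for c in rhs.split("+") if c.strip())
    try:
        return CombinationRule(kind, pattern, replacement, priority)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: {exc}") from exc


def parse_rules(path: str | Path) -> list[CombinationRule]:
    """Read and validate a rules file; order = priority, then file order."""
    rules: list[CombinationRule] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            rules.append(_parse_line(line, lineno))
    # stable sort: equal priorities keep file order
    return sorted(rules, key=lambda r: r.priority)


def apply_rules(codes: Iterable[str], rules: Sequence[CombinationRule]) -> set[str]:
    """Apply each rule once, in order, to a predicted code set."""
    out = set(codes)
    for rule in rules:
        if rule.kind == "combine":
            if rule.pattern <= out:
                out -= rule.pattern
                out |= set(rule.replacement)
        else:  # split
            (code,) = rule.pattern
            if code in out:
                out.discard(code)
                out |= set(rule.replacement)
    return out
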