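"""Domain and ordinal-level vocabulary shared by every stage.

Health status is recorded on a fixed set of named *domains* (personal
functioning, psychological distress, nutrition, physical activity, sleep,
social support, substance use), each taking one of three ordered levels:
``poor`` < ``fair`` < ``healthy``.  The registry order is fixed and is used
throughout for deterministic tie-breaking and for the canonical node order
of the two-slice graphical model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "LEVELS",
    "LEVEL_CODES",
    "POOR",
    "FAIR",
    "HEALTHY",
    "DEFAULT_DOMAINS",
    "DomainRegistry",
    "ProfileState",
    "normalize_level",
]

#: Ordinal level labels, worst to best.  Index in this tuple is the code.
LEVELS: tuple[str, str, str] = ("poor", "fair", "healthy")
LEVEL_CODES: Mapping[str, int] = {lbl: i for i, lbl in enumerate(LEVELS)}
POOR, FAIR, HEALTHY = 0, 1, 2

#: Canonical seven-domain registry, in fixed documented order.
DEFAULT_DOMAINS: tuple[str, ...] = (
    "functioning",
    "distress",
    "nutrition",
    "activity",
    "sleep",
    "social",
    "substance",
)


def normalize_level(label: str) -> int:
    """Map a level label to its ordinal code, case-insensitively.

    Raises :class:`ValueError` for unknown labels.
    """
    key = str(label).strip().lower()
    try:
        return LEVEL_CODES[key]
    except KeyError:
        raise ValueError(
            f"unknown level label {label!r}; expected one of {LEVELS}"
        ) from None


@dataclass(frozen=True)
class DomainRegistry:
    """Ordered, unique collection of domain names.

    The order is significant: it defines node order in the temporal graph
    and the documented tie-break order for rankings.
    """

    names: tuple[str, ...] = DEFAULT_DOMAINS

    def __post_init__(self) -> None:
        if len(self.names) == 0:
            raise ValueError("registry must contain at least one domain")
        if len(set(self.names)) != len(self.names):
            raise ValueError(f"duplicate domain names in registry: {self.names}")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"domain {name!r} not in registry {self.names}") from None


@dataclass(frozen=True)
class ProfileState:
    """Per-domain level codes at a single time point.

    ``levels[i]`` is the ordinal code of the i-th registry domain.
    """

    registry: DomainRegistry
    levels: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.registry):
            raise ValueError(
                f"expected {len(self.registry)} levels, got {len(self.levels)}"
            )
        for code in self.levels:
            if code not in (0, 1, 2):
                raise ValueError(f"invalid level code {code!r}")

    @classmethod
    def from_labels(
        cls, registry: DomainRegistry, labels: Mapping[str, str] | Sequence[str]
    ) -> "ProfileState":
        """Build a state from level labels, keyed by domain or in registry order."""
        if isinstance(labels, Mapping):
            missing = [d for d in registry if d not in labels]
            if missing:
                raise ValueError(f"missing domains in state: {missing}")
            codes = tuple(normalize_level(labels[d]) for d in registry)
        else:
            codes = tuple(normalize_level(x) for x in labels)
        return cls(registry, codes)

    def level(self, domain: str) -> int:
        return self.levels[self.registry.index(domain)]

    def label(self, domain: str) -> str:
        return LEVELS[self.level(domain)]

    def labels(self) -> dict[str, str]:
        return {d: LEVELS[c] for d, c in zip(self.registry, self.levels)}

    def replace(self, domain: str, code: int) -> "ProfileState":
        i = self.registry.index(domain)
        levels = list(self.levels)
        levels[i] = code
        return ProfileState(self.registry, tuple(levels))


def all_profile_states(registry: DomainRegistry) -> Iterable[ProfileState]:
    """Iterate over every possible profile state (3**k of them)."""
    import itertools

    for combo in itertools.product((0, 1, 2), repeat=len(registry)):
        yield ProfileState(registry, combo)
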