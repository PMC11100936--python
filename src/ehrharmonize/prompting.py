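"""Prompt construction for generative gap filling, plus the provider contract.

The zero-shot prompt lists the patient's K interval visits in order, marks
gaps with the literal token ``MISSING`` (exactly once per gap), states the
six-month spacing, and asks for one doctor's note per gap about the
patient's symptoms and treatment plans.  The one-shot prompt prepends a
worked example: a single visit note and, as the answer, the note from the
subsequent visit six months later.

Generated notes are returned under a ``### NOTE <slot>`` delimiter protocol
(one block per missing slot) so they can be parsed deterministically; real
LLM APIs rarely guarantee structure, hence the retry/fallback logic in the
harmonization layer.  The bundled :class:`MockProvider` is seeded and
deterministic: it synthesizes each missing note by remixing the nearest
observed note in the prompt.  Adapters for hosted models can be registered
under the same contract; they are deliberately not imported by default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Optional, Protocol, Sequence

import numpy as np

MISSING_TOKEN = "MISSING"
NOTE_DELIM = "### NOTE"


class PromptError(ValueError):
    """Raised for invalid prompt construction inputs."""


class GenerationParseError(RuntimeError):
    """Raised when provider output does not follow the delimiter protocol."""


@dataclass(frozen=True)
class PromptBundle:
    mode: str  # "zero_shot" | "one_shot"
    text: str
    missing_slot_ids: tuple[int, ...]
    example_pair: Optional[tuple[str, str]] = None


def _visit_lines(slot_texts: Sequence[Optional[str]]) -> list[str]:
    lines = []
    for i, text in enumerate(slot_texts):
        month = i * 6
        body = MISSING_TOKEN if text is None else text.strip()
        lines.append(f"Visit {i + 1} (month {month}): {body}")
    return lines


def _task_block(slot_texts: Sequence[Optional[str]]) -> tuple[str, tuple[int, ...]]:
    missing = tuple(i for i, t in enumerate(slot_texts) if t is None)
    if not missing:
        raise PromptError("no missing slots: nothing to generate")
    slot_list = ", ".join(str(i + 1) for i in missing)
    lines = [
        "The following are a patient's medical visits. Each visit occurs at "
        "six-month intervals. Visits without an available note carry a "
        "marker token instead of text.",
        "",
        *_visit_lines(slot_texts),
        "",
        "For each marked visit, generate a doctor's note about the patient's "
        "symptoms and treatment plans based on the information from the "
        "existing visits.",
        "Return exactly one note per marked visit, each introduced by a "
        f"line '{NOTE_DELIM} <visit number>' (visits {slot_list}).",
    ]
    return "\n".join(lines), missing


def build_zero_shot(slot_texts: Sequence[Optional[str]]) -> PromptBundle:
    """Zero-shot prompt for a K-slot grid (``None`` marks a gap)."""
    text, missing = _task_block(slot_texts)
    return PromptBundle("zero_shot", text, missing)


def build_one_shot(
    example: tuple[str, str], slot_texts: Sequence[Optional[str]]
) -> PromptBundle:
    """One-shot prompt: worked example block followed by the zero-shot task.

    The example pairs a single visit note with the note from the subsequent
    visit six months later.
    """
    note, next_note = example
    if not note.strip() or not next_note.strip():
        raise PromptError("one-shot example texts must be nonempty")
    task, missing = _task_block(slot_texts)
    example_block = "\n".join(
        [
            "Example. A patient's visit note:",
            note.strip(),
            "The doctor's note from the subsequent visit six months later:",
            next_note.strip(),
            "",
        ]
    )
    return PromptBundle("one_shot", example_block + "\n" + task, missing, (note, next_note))


class TextGenerationProvider(Protocol):
    """Contract: prompt -> generated text.

    Implementations must document their determinism; the bundled mock is
    fully deterministic given its seed.
    """

    def generate(self, prompt: str) -> str: ...


_VISIT_LINE = re.compile(r"^Visit (\d+) \(month \d+\): (.*)$", re.M)


class MockProvider:
    """Deterministic stand-in generator.

    Parses the visit lines out of the prompt and, for each slot marked
    ``MISSING``, emits a note remixing the nearest observed note (preferring
    the most recent earlier visit), prefixed with an interval follow-up
    sentence.  Output follows the ``### NOTE i`` protocol.
    """

    def __init__(self, seed: int = 0, max_words: int = 80):
        self.seed = seed
        self.max_words = max_words

    def generate(self, prompt: str) -> str:
        slots: dict[int, Optional[str]] = {}
        for m in _VISIT_LINE.finditer(prompt):
            idx = int(m.group(1)) - 1
            body = m.group(2).strip()
            slots[idx] = None if body == MISSING_TOKEN else body
        observed = sorted(i for i, t in slots.items() if t is not None)
        missing = sorted(i for i, t in slots.items() if t is None)
        rng = np.random.default_rng([self.seed, len(prompt) % (2**16)])
        blocks = []
        for i in missing:
            earlier = [j for j in observed if j < i]
            source = max(earlier) if earlier else min(observed) if observed else None
            if source is None:
                body = "no prior information available; routine follow up advised."
            else:
                words = slots[source].split()
                if len(words) > self.max_words:
                    start = int(rng.integers(0, len(words) - self.max_words + 1))
                    words = words[start : start + self.max_words]
                body = (
                    f"interval follow up approximately six months after visit "
                    f"{source + 1}. " + " ".join(words)
                )
            blocks.append(f"{NOTE_DELIM} {i + 1}\n{body}")
        return "\n".join(blocks)


_NOTE_BLOCK = re.compile(rf"^{re.escape(NOTE_DELIM)} (\d+)\s*$", re.M)


def parse_generated(output: str, missing_slot_ids: Sequence[int]) -> dict[int, str]:
    """Split provider output into one note per missing slot.

    Raises :class:`GenerationParseError` when the delimiter blocks do not
    cover exactly the requested slots.
    """
    matches = list(_NOTE_BLOCK.finditer(output))
    notes: dict[int, str] = {}
    for k, m in enumerate(matches):
        slot = int(m.group(1)) - 1
        end = matches[k + 1].start() if k + 1 < len(matches) else len(output)
        notes[slot] = output[m.end() : end].strip()
    expected = set(missing_slot_ids)
    if set(notes) != expected or any(not t for t in notes.values()):
        raise GenerationParseError(
            f"expected one nonempty note per slot {sorted(expected)}, "
            f"got blocks for {sorted(notes)}"
        )
    return notes


_GEN_PROVIDERS: dict[str, Callable[..., TextGenerationProvider]] = {
    "mock": MockProvider,
}


def register_generation_provider(
    name: str, factory: Callable[..., TextGenerationProvider]
) -> None:
    _GEN_PROVIDERS[name] = factory


def get_generation_provider(name: str, **kwargs) -> TextGenerationProvider:
    try:
        return _GEN_PROVIDERS[name](**kwargs)
    except KeyError:
        raise PromptError(
            f"unknown generation provider {name!r}; registered: "
            f"{sorted(_GEN_PROVIDERS)}"
        ) from None
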