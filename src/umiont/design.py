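"""Degenerate UMI tag designs and their collision statistics.

A UMI design is a pattern over {A,C,G,T,V}: fixed bases are emitted
literally, each ``V`` is drawn uniformly from the three-letter alphabet
{A,C,G}.  The default design carries 16 variable positions interleaved with
T spacers, giving 3^16 ~ 43 million distinct tags, so that two independent
template molecules essentially never receive tags within the 2-edit radius
used for cluster splitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._align import edit_distance

#: alphabet used at variable positions (3 letters by construction)
VARIABLE_ALPHABET = "ACG"

#: default tag pattern: 16 variable positions in T-spacered blocks
DEFAULT_PATTERN = "TTTVVVVTTVVVVTTVVVVTTVVVVTTT"


@dataclass(frozen=True)
class UmiDesign:
    """A degenerate tag design.

    Parameters
    ----------
    pattern:
        String over {A,C,G,T,V}; ``V`` marks a variable position.
    """

    pattern: str = DEFAULT_PATTERN
    variable_alphabet: str = field(default=VARIABLE_ALPHABET)

    def __post_init__(self):
        bad = set(self.pattern) - set("ACGTV")
        if bad:
            raise ValueError(f"pattern contains invalid symbols: {sorted(bad)}")

    @property
    def n_variable(self) -> int:
        return self.pattern.count("V")

    @property
    def length(self) -> int:
        return len(self.pattern)

    @property
    def n_sequences(self) -> int:
        """Number of distinct realizable tags (|alphabet|^n_variable)."""
        return len(self.variable_alphabet) ** self.n_variable


def draw_umi(design: UmiDesign, rng: np.random.Generator) -> str:
    """Draw one tag: fixed positions literal, each V uniform over the alphabet."""
    return draw_umis(design, 1, rng)[0]


def draw_umis(design: UmiDesign, n: int, rng: np.random.Generator) -> list[str]:
    """Vectorized draw of ``n`` tags."""
    k = design.n_variable
    if k == 0:
        return [design.pattern] * n
    alphabet = np.frombuffer(design.variable_alphabet.encode(), dtype=np.uint8)
    template = np.frombuffer(design.pattern.encode(), dtype=np.uint8)
    v_idx = np.flatnonzero(template == ord("V"))
    out = np.tile(template, (n, 1))
    out[:, v_idx] = alphabet[rng.integers(0, len(alphabet), size=(n, k))]
    return [row.tobytes().decode() for row in out]


def _variable_strings(design: UmiDesign, n: int, rng: np.random.Generator) -> list[str]:
    """Draw only the variable-position strings (the tag's information content)."""
    k = design.n_variable
    alphabet = np.frombuffer(design.variable_alphabet.encode(), dtype=np.uint8)
    draws = alphabet[rng.integers(0, len(alphabet), size=(n, k))]
    return [row.tobytes().decode() for row in draws]


def wilson_interval(k: int, n: int, z: float = 1.959964) -> tuple[float, float]:
    """Wilson 95% score interval for a binomial proportion k/n."""
    if n == 0:
        return (0.0, 1.0)
    p = k / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def estimate_collision_probability(
    design: UmiDesign,
    n_pairs: int = 1_000_000,
    max_edit: int = 2,
    seed: int | None = None,
    distance: str = "levenshtein",
):
    """Monte-Carlo estimate of the tag collision probability.

    Draws ``n_pairs`` independent pairs of variable-position strings and
    reports the fraction within edit distance ``max_edit`` of each other --
    the probability that two distinct template molecules would be merged by
    the cluster-splitting rule.  Fixed spacer positions are identical by
    construction and carry no information, so only variable positions enter.

    Parameters
    ----------
    distance:
        ``"levenshtein"`` (default) or ``"hamming"`` (substitution-only, for
        which a closed form exists and serves as a cross-check).

    Returns
    -------
    (estimate, (ci_low, ci_high)) with a Wilson 95% interval.
    """
    if n_pairs < 10**5:
        raise ValueError("n_pairs must be at least 1e5 for a stable estimate")
    rng = np.random.default_rng(seed)
    if max_edit >= design.n_variable:
        return 1.0, (1.0, 1.0)
    hits = 0
    chunk = 200_000
    done = 0
    while done < n_pairs:
        m = min(chunk, n_pairs - done)
        a = _variable_strings(design, m, rng)
        b = _variable_strings(design, m, rng)
        if distance == "hamming":
            for x, y in zip(a, b):
                d = sum(cx != cy for cx, cy in zip(x, y))
                if d <= max_edit:
                    hits += 1
        else:
            for x, y in zip(a, b):
                if edit_distance(x, y, k=max_edit) != -1:
                    hits += 1
        done += m
    return hits / n_pairs, wilson_interval(hits, n_pairs)


def hamming_collision_closed_form(design: UmiDesign, max_edit: int) -> float:
    """Exact P(substitution distance <= max_edit) for two independent tags.

    Positions agree with probability 1/|alphabet| independently, so the
    distance is Binomial(n_variable, 1 - 1/|alphabet|).
    """
    from scipy.stats import binom

    a = len(design.variable_alphabet)
    return float(binom.cdf(max_edit, design.n_variable, 1 - 1 / a))
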