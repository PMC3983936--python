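"""Deterministic synthetic feature sets for testing and demos.

The generator emulates a UniProt-style single-protein annotation set:
a mix of region features (peptides, domains, disulfide bonds) whose
lengths follow a geometric distribution (many short regions, a long
tail), and single-residue sites (metal binding, active sites, PTMs)
placed uniformly along the sequence. The default type vocabulary covers
every glyph-triggering label so all drawing paths are exercised. Overlap
depth is capped by rejection sampling, so fixtures stay renderable in a
bounded number of tracks.

Randomness comes from ``numpy.random.default_rng`` seeded explicitly —
the same seed yields the same collection on any platform.
"""
from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import FeasibilityError
from .model import Feature

#: (type_label, type_category, type_code, is_site) — labels chosen so the
#: default-glyph rules hit circle, diamond, wave, hexagon, triangle,
#: bridge, rect and line.
DEFAULT_TYPE_VOCABULARY: Tuple[Tuple[str, str, str, bool], ...] = (
    ("Metal ion binding", "Binding site", "SO:0001092", True),
    ("Active site", "Catalytic site", "SO:0001104", True),
    ("Lipidation", "PTM", "SO:0001175", True),
    ("Glycosylation", "PTM", "SO:0001428", True),
    ("Modified residue", "PTM", "SO:0001089", True),
    ("Site", "Functional site", "SO:0000839", True),
    ("Disulfide bond", "PTM", "SO:0001088", False),
    ("Peptide", "Molecule processing", "SO:0001064", False),
    ("Domain", "Family & domain", "SO:0000417", False),
)

_MEAN_REGION_LENGTH = 25  # residues; geometric tail like real domain sets
_MAX_ATTEMPTS = 200


def generate_fixture(
    n_features: int,
    sequence_length: int,
    max_depth: int = 5,
    type_vocabulary: Optional[Sequence[Tuple[str, str, str, bool]]] = None,
    seed: int = 0,
) -> List[Feature]:
    """Generate ``n_features`` reproducible features on one sequence.

    Interval starts are uniform over the sequence; region lengths are
    geometric with mean ~25 residues, capped at a quarter of the
    sequence. A candidate pushing the overlap depth anywhere above
    ``max_depth`` is rejected and redrawn; if no placement is found in
    200 attempts (or the request is impossible outright), a
    :class:`FeasibilityError` is raised.
    """
    if n_features < 0:
        raise FeasibilityError("n_features must be >= 0")
    if max_depth < 1:
        raise FeasibilityError("max_depth must be >= 1")
    if sequence_length < 1:
        raise FeasibilityError("sequence_length must be >= 1")
    if n_features > sequence_length * max_depth:
        raise FeasibilityError(
            f"{n_features} features cannot fit in {sequence_length} residues "
            f"at depth <= {max_depth}"
        )
    vocab = list(type_vocabulary or DEFAULT_TYPE_VOCABULARY)
    rng = np.random.default_rng(seed)
    depth = np.zeros(sequence_length + 1, dtype=np.int32)  # 1-based

    features: List[Feature] = []
    for i in range(n_features):
        for _ in range(_MAX_ATTEMPTS):
            type_label, category, code, is_site = vocab[
                int(rng.integers(len(vocab)))
            ]
            if is_site:
                start = int(rng.integers(1, sequence_length + 1))
                end = start
            else:
                length = 1 + int(rng.geometric(1 / _MEAN_REGION_LENGTH))
                length = min(length, max(1, sequence_length // 4),
                             sequence_length)
                start = int(rng.integers(1, sequence_length - length + 2))
                end = start + length - 1
            if int(depth[start:end + 1].max()) < max_depth:
                depth[start:end + 1] += 1
                break
        else:
            raise FeasibilityError(
                f"could not place feature {i} within depth {max_depth} "
                f"after {_MAX_ATTEMPTS} attempts"
            )
        slug = type_label.upper().replace(" ", "_")
        features.append(
            Feature(
                feature_id=f"SYN_{slug}_{start}_{end}_{i}",
                start=start,
                end=end,
                type_label=type_label,
                type_code=code,
                type_category=category,
                feature_label=f"{type_label} {start}-{end}",
                evidence_text="synthetic",
            )
        )
    return features
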