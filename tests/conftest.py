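import random

import pytest

from featuretracks import Feature, GlyphKind, LayoutConfig, build_layout


@pytest.fixture
def peptide_feature():
    """The Q8LAX3 elicitor peptide region, residues 74-96."""
    return Feature(
        feature_id="UPKB_Q8LAX3_PEPTIDE_74_96",
        start=74,
        end=96,
        type_label="active_peptide",
        type_code="SO:0001064",
        type_category="Molecule processing",
        feature_label="Elicitor peptide 3",
        evidence_text="UniProt",
        color="#7DBAA4",
    )


@pytest.fixture
def q8lax3_config():
    """700 px canvas, 20 px margins, full 96-residue window."""
    return LayoutConfig(sequence_length=96)


@pytest.fixture
def q8lax3_doc(peptide_feature, q8lax3_config):
    return build_layout("Q8LAx3", [peptide_feature], q8lax3_config)


@pytest.fixture
def three_listing_features():
    """The three mutually overlapping a4_human features (54-96, 74-96,
    75-96): a blue peptide, a diamond-hinted active site, and a green
    disulfide bridge."""
    common = dict(
        type_code="SO:0001064",
        type_category="Molecule processing",
        feature_label="Elicitor peptide 3",
        evidence_text="UniProt",
    )
    return [
        Feature(feature_id="UNIPROTKB_Q8LAX3_PEPTIDE_54_96", start=54,
                end=96, type_label="Peptide", color="blue", **common),
        Feature(feature_id="UNIPROTKB_Q8LAX3_PEPTIDE_74_96", start=74,
                end=96, type_label="Active Site",
                shape_hint=GlyphKind.DIAMOND, **common),
        Feature(feature_id="UPKB_Q8LAX3_DISULFID_75_96", start=75, end=96,
                type_label="Active Site", color="#33FF66",
                shape_hint=GlyphKind.BRIDGE, **common),
    ]


def random_intervals(rng: random.Random, n_max=30, length=300):
    """Random closed intervals on [1, length] for oracle comparisons."""
    n = rng.randint(0, n_max)
    out = []
    for i in range(n):
        s = rng.randint(1, length)
        e = min(length, s + rng.randint(0, 40))
        out.append(
            Feature(feature_id=f"r{i}", start=s, end=e, type_label="Region")
        )
    return out


def residue_depth(features, length):
    """Independent brute-force oracle: maximum number of features
    covering any single residue."""
    counts = [0] * (length + 2)
    for f in features:
        for p in range(f.start, f.end + 1):
            counts[p] += 1
    return max(counts) if features else 0
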