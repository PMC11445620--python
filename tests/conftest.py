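"""Shared fixtures: the bundled allergy-mini bundle, tiny hand-built
terminologies, and a pipeline over the bundle."""

from __future__ import annotations

import os

import pytest

from pcebridge.fixtures import build_allergy_mini
from pcebridge.pipeline import Pipeline, PipelineConfig
from pcebridge.terminology import IS_A, ConceptRecord, RelationshipRecord, Terminology


def build_term(
    parent_map: dict[str, list[str]],
    fully_defined: set[str] = frozenset(),
    definitions: dict[str, list[tuple[str, str, int]]] | None = None,
    inactive: set[str] = frozenset(),
) -> Terminology:
    """Construct a terminology directly from a child->parents map.

    ``definitions`` adds defining (attribute, value, group) rows; group 0
    means ungrouped.  Attribute/value ids must appear in ``parent_map``.
    """
    parent_map = dict(parent_map)
    if IS_A not in parent_map:  # the is-a metadata concept must exist
        root = next(cid for cid, parents in parent_map.items() if not parents)
        parent_map[IS_A] = [root]
    concepts = {
        cid: ConceptRecord(
            id=cid, fsn=f"concept {cid}", active=cid not in inactive,
            fully_defined=cid in fully_defined,
        )
        for cid in parent_map
    }
    rels = [
        RelationshipRecord(child, IS_A, parent, 0, True)
        for child, parents in parent_map.items()
        for parent in parents
    ]
    for cid, rows in (definitions or {}).items():
        for attr, value, group in rows:
            rels.append(RelationshipRecord(cid, attr, value, group, True))
    return Terminology(concepts, rels)


@pytest.fixture(scope="session")
def mini(tmp_path_factory):
    return build_allergy_mini(str(tmp_path_factory.mktemp("allergy-mini")))


@pytest.fixture(scope="session")
def term(mini):
    return mini.terminology


@pytest.fixture(scope="session")
def pipeline(mini):
    return Pipeline(
        PipelineConfig(
            terminology_dir=os.path.join(mini.directory, "rf2"),
            mrcm_path=mini.mrcm_path,
            categories_path=mini.categories_path,
            maps_dir=mini.maps_dir,
            profile_set="nashp-like",
        )
    )


@pytest.fixture(scope="session")
def mii_pipeline(mini):
    return Pipeline(
        PipelineConfig(
            terminology_dir=os.path.join(mini.directory, "rf2"),
            mrcm_path=mini.mrcm_path,
            categories_path=mini.categories_path,
            maps_dir=mini.maps_dir,
            profile_set="mii-like",
        )
    )


@pytest.fixture()
def chain_term():
    # root <- A <- B
    return build_term({"100001": [], "100002": ["100001"], "100003": ["100002"]})


@pytest.fixture()
def diamond_term():
    # B below A1 and A2, both below root
    return build_term(
        {
            "100001": [],
            "100002": ["100001"],
            "100003": ["100001"],
            "100004": ["100002", "100003"],
        }
    )
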