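"""Methylation-expression integration and the published diagnostic signature.

Crossing the differential-expression direction (up/down) with the
differential-methylation call (hypo/hyper) yields four gene groups. Under
the negative-coupling expectation the biologically concordant ones are
*hypo-up* (hypo-methylated, up-regulated) and *hyper-down* (hyper-methylated,
down-regulated); the discordant hyper-up and hypo-down groups are kept for
the region-distribution tabulation.

The module also ships, as checksummed plain-text fixtures, the published
blood diagnostic signature for major depressive disorder: 46 hypo-up genes
and 71 hyper-down genes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd

from .synthetic import REGIONS


class CorruptedFixtureError(RuntimeError):
    """A packaged fixture does not match its recorded SHA-256 checksum."""


@dataclass(frozen=True)
class IntegrationGroups:
    """The four DEG x DMG direction groups (pairwise disjoint gene sets)."""

    hypo_up: frozenset
    hyper_down: frozenset
    hyper_up: frozenset
    hypo_down: frozenset

    def as_dict(self) -> dict[str, set]:
        return {
            "hypo_up": set(self.hypo_up),
            "hyper_down": set(self.hyper_down),
            "hyper_up": set(self.hyper_up),
            "hypo_down": set(self.hypo_down),
        }


def intersect_groups(up: set, down: set, hypo: set, hyper: set) -> IntegrationGroups:
    """Exact set intersections per direction pairing."""
    return IntegrationGroups(
        hypo_up=frozenset(up & hypo),
        hyper_down=frozenset(down & hyper),
        hyper_up=frozenset(up & hyper),
        hypo_down=frozenset(down & hypo),
    )


def region_distribution(
    groups: IntegrationGroups, region_calls: Mapping[str, set]
) -> pd.DataFrame:
    """Per-group, per-region gene counts (4 groups x 6 regions).

    ``region_calls`` maps each grouped gene to the set of regions in which it
    carries a differential-methylation signal; a gene with several such
    regions counts once in each region column.
    """
    rows = {}
    for name, genes in groups.as_dict().items():
        counts = dict.fromkeys(REGIONS, 0)
        for gene in genes:
            if gene not in region_calls:
                raise KeyError(f"gene {gene!r} is grouped but has no region calls")
            for region in region_calls[gene]:
                if region in counts:
                    counts[region] += 1
        rows[name] = counts
    table = pd.DataFrame(rows).T.loc[["hypo_up", "hypo_down", "hyper_up", "hyper_down"]]
    return table[list(REGIONS)].rename_axis("group")


def _read_fixture(name: str, manifest: dict[str, str]) -> pd.DataFrame:
    data = resources.files("methdx.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != manifest[name]:
        raise CorruptedFixtureError(
            f"{name}: sha256 {digest} does not match manifest {manifest[name]}"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(data), sep="\t")


def load_signature_fixture(raw: bool = False) -> tuple[list[str], list[str]]:
    """The published 46-gene hypo-up and 71-gene hyper-down signature lists.

    Ordered by expression-classifier importance (descending), as printed.
    ``raw=True`` returns the symbols exactly as printed (including the
    mangled tokens such as ``X4.SEP`` and dot-separated HLA names);
    by default the canonicalised symbols (SEPT4, NKX3-2, HLA-DQA2) are
    returned. Fixture integrity is verified against a SHA-256 manifest.
    """
    manifest = json.loads(
        resources.files("methdx.data").joinpath("signature_manifest.json").read_text()
    )
    col = "raw" if raw else "canonical"
    hypo_up = _read_fixture("hypo_up_signature.tsv", manifest)[col].tolist()
    hyper_down = _read_fixture("hyper_down_signature.tsv", manifest)[col].tolist()
    return hypo_up, hyper_down
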