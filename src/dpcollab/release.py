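"""K-repetition synthetic-data release and combined-set assembly.

Each party draws K parameter vectors from its fitted posterior, samples one
synthetic replicate of size N per draw, and publishes the K replicates (with a
manifest). A recipient combines its own local data with the k-th replicate of
every *other* party to form the k-th of K combined training sets; a party's
own synthetic data never enters its combined sets. Records carry internal
provenance tags (party id, replicate id) so this exclusion is assertable;
tags are stripped on CSV export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .datasets import TabularDataset, concat_datasets
from .model import sample_synthetic
from .rng import stream
from .transforms import MeanFieldPosterior

__all__ = ["ReleaseBundle", "release_synthetic_sets", "assemble_combined_sets"]

LOCAL_PARTY = -1  # provenance party id marking real (non-synthetic) records


@dataclass(frozen=True)
class ReleaseBundle:
    """The published artifact of one party: K synthetic replicates of size N."""

    party: int
    replicates: tuple[TabularDataset, ...]
    n_per_replicate: int
    seed: int
    realized_epsilon: float | None = None

    def __post_init__(self) -> None:
        for rep in self.replicates:
            if rep.n != self.n_per_replicate:
                raise ValueError("replicate size differs from declared N")

    @property
    def k(self) -> int:
        return len(self.replicates)

    def export(self, directory: str | Path) -> None:
        """Write replicates as CSV plus a plain-text manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, rep in enumerate(self.replicates):
            rep.to_csv(directory / f"party{self.party}_replicate{i}.csv")
        manifest = {
            "party": self.party,
            "k": self.k,
            "n_per_replicate": self.n_per_replicate,
            "seed": self.seed,
            "realized_epsilon": self.realized_epsilon,
        }
        (directory / f"party{self.party}_manifest.json").write_text(
            json.dumps(manifest, indent=1))


def release_synthetic_sets(post: MeanFieldPosterior, k: int, n: int,
                           seed: int, party: int = 0,
                           realized_epsilon: float | None = None
                           ) -> ReleaseBundle:
    """Draw K posterior parameter vectors and one size-N replicate per draw.

    N conventionally equals the releasing party's local training size. Pure
    function of (posterior, k, n, seed).
    """
    if k < 1 or n < 1:
        raise ValueError("need k >= 1 and n >= 1")
    if not np.all(np.isfinite(post.loc)) or not np.all(np.isfinite(post.log_scale)):
        raise ValueError("posterior has non-finite parameters")
    enc = post.layout.encoding
    reps = []
    for i in range(k):
        rng = stream(seed, f"release-party{party}-rep{i}")
        params = post.draw_params(rng)
        reps.append(
            sample_synthetic(params, n, enc, rng).with_provenance(party, i))
    return ReleaseBundle(party, tuple(reps), n, seed, realized_epsilon)


def assemble_combined_sets(local_train: TabularDataset,
                           shared: Mapping[int, ReleaseBundle], k: int,
                           own_party: int | None = None
                           ) -> list[TabularDataset]:
    """Build the K combined training sets for one recipient.

    The k-th combined set is the recipient's local data plus replicate k from
    every other party's bundle. ``own_party`` (if given) is excluded — a party
    never trains on its own synthetic release.
    """
    if k < 1:
        raise ValueError("need k >= 1")
    others = {pid: b for pid, b in shared.items() if pid != own_party}
    for pid, bundle in others.items():
        if bundle.k < k:
            raise ValueError(f"party {pid} shared only {bundle.k} replicates, "
                             f"need {k}")
    tagged_local = local_train.with_provenance(LOCAL_PARTY, -1)
    return [
        concat_datasets([tagged_local]
                        + [others[pid].replicates[i] for pid in sorted(others)])
        for i in range(k)
    ]
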