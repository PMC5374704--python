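"""Synthetic protein-RNA interactomes with planted similarity structure.

The generator encodes the statistical premise of similarity-based negative
selection — similar proteins tend to share RNA partners — as ground truth:

* proteins fall into groups; each group descends from one random ancestral
  sequence (length 50-300) by independent per-site substitution at
  ``mutation_rate``, and shares a core set of GO terms and domain
  identifiers plus per-protein private noise terms;
* each RNA (length 20-200 over A/U/C/G) truly interacts with every protein
  of 1-2 randomly assigned groups;
* the *observed* positive set is a uniform subsample of the true
  interactions at ``observation_fraction`` — the unobserved remainder is
  exactly the contamination a naive random negative sampler risks picking.

``contamination_rate`` measures the fraction of a constructed negative set
that consists of hidden true interactions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import ValidationError
from .io_formats import (
    AnnotationTable,
    InteractionSet,
    ProteinRecord,
    RnaRecord,
    write_annotations,
    write_fasta,
    write_pairs,
)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
RNA_BASES = np.array(list("ACGU"))


@dataclass
class SyntheticWorld:
    proteins: list[ProteinRecord]
    rnas: list[RnaRecord]
    go: AnnotationTable
    domains: AnnotationTable
    truth: InteractionSet
    observed: InteractionSet
    group_of: dict[str, int]
    params: dict


def generate_world(
    n_groups: int = 5,
    proteins_per_group: int = 8,
    n_rnas: int = 40,
    mutation_rate: float = 0.1,
    observation_fraction: float = 0.6,
    seed: int = 0,
) -> SyntheticWorld:
    """Generate one reproducible synthetic interactome.

    Defaults describe a small but structured world: 5 similarity groups of
    8 proteins, 40 RNAs, 10% per-site divergence within a group, and 60%
    of true interactions observed.
    """
    if min(n_groups, proteins_per_group, n_rnas) < 1:
        raise ValidationError("all counts must be >= 1")
    if not 0.0 <= mutation_rate < 1.0:
        raise ValidationError("mutation_rate must be in [0, 1)")
    if not 0.0 < observation_fraction <= 1.0:
        raise ValidationError("observation_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)

    proteins: list[ProteinRecord] = []
    group_of: dict[str, int] = {}
    go: dict[str, frozenset[str]] = {}
    domains: dict[str, frozenset[str]] = {}
    members: dict[int, list[str]] = {}
    for g in range(n_groups):
        length = int(rng.integers(50, 301))
        ancestor = rng.choice(AMINO_ACIDS, size=length)
        core_go = {f"GO:G{g}:{t}" for t in range(6)}
        core_dom = {f"PF:G{g}:{t}" for t in range(3)}
        members[g] = []
        for m in range(proteins_per_group):
            seq = ancestor.copy()
            mutate = rng.random(length) < mutation_rate
            if mutate.any():
                # shift within the alphabet guarantees a different residue
                idx = np.searchsorted(AMINO_ACIDS, seq[mutate])
                shift = rng.integers(1, len(AMINO_ACIDS), size=int(mutate.sum()))
                seq[mutate] = AMINO_ACIDS[(idx + shift) % len(AMINO_ACIDS)]
            pid = f"prot_g{g}m{m}"
            proteins.append(ProteinRecord(pid, "".join(seq)))
            group_of[pid] = g
            members[g].append(pid)
            go[pid] = frozenset(core_go | {f"GO:{pid}:{t}" for t in range(2)})
            domains[pid] = frozenset(core_dom | {f"PF:{pid}:0"})

    rnas: list[RnaRecord] = []
    truth: set[tuple[str, str]] = set()
    for r in range(n_rnas):
        length = int(rng.integers(20, 201))
        rid = f"rna{r:03d}"
        rnas.append(RnaRecord(rid, "".join(rng.choice(RNA_BASES, size=length))))
        n_assigned = int(rng.integers(1, min(2, n_groups) + 1))
        for g in rng.choice(n_groups, size=n_assigned, replace=False):
            for pid in members[int(g)]:
                truth.add((pid, rid))

    truth_sorted = sorted(truth)
    n_obs = max(1, int(round(observation_fraction * len(truth_sorted))))
    obs_idx = rng.choice(len(truth_sorted), size=n_obs, replace=False)
    observed = frozenset(truth_sorted[i] for i in obs_idx)

    return SyntheticWorld(
        proteins=proteins,
        rnas=rnas,
        go=AnnotationTable(go, "go"),
        domains=AnnotationTable(domains, "domain"),
        truth=InteractionSet(frozenset(truth), "positive"),
        observed=InteractionSet(observed, "positive"),
        group_of=group_of,
        params=dict(
            n_groups=n_groups,
            proteins_per_group=proteins_per_group,
            n_rnas=n_rnas,
            mutation_rate=mutation_rate,
            observation_fraction=observation_fraction,
            seed=seed,
        ),
    )


def contamination_rate(negatives: InteractionSet, world: SyntheticWorld) -> float:
    """Fraction of a negative set that is secretly a true interaction."""
    if len(negatives) == 0:
        raise ValidationError("contamination undefined for an empty negative set")
    return len(negatives.pairs & world.truth.pairs) / len(negatives)


def write_world(world: SyntheticWorld, outdir: str | Path) -> None:
    """Serialize a world: FASTA sequences, annotation tables, the observed
    positive pairs, and the hidden truth pairs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(world.proteins, outdir / "proteins.fasta")
    write_fasta(world.rnas, outdir / "rnas.fasta")
    write_annotations(world.go, outdir / "go.tsv")
    write_annotations(world.domains, outdir / "domains.tsv")
    write_pairs(world.observed, outdir / "positives.tsv")
    write_pairs(world.truth, outdir / "truth.tsv")
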