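"""Seeded multi-species reaction-set generator with planted structure.

The generator emulates the layered organisation observed in plant
metabolism: a small pool of ubiquitously reused currency metabolites (ATP,
H2O, NAD+, ... in real data) that every species shares; shared primary
pathways (linear reaction chains) whose reactions each carry currency
metabolites on both sides; and species-specific secondary pathways —
linear chains hanging off a primary metabolite — that only occasionally
touch a currency metabolite. Under the substrate-product model the
currency pool becomes the densely interlinked centre, so the maximum
k-core of every species recovers the planted currency set, the shared
(currency + primary) metabolism fills the inner cores, and secondary
chains sit in the outermost shells. Currency attachment to primary
reactions is round-robin rather than uniform so every currency metabolite
meets the degree floor that pins it to the inner core even at small
sizes.

All randomness flows through one ``random.Random`` seeded from the
config; the same seed yields byte-identical fixture files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from metacore.reactions import Reaction, write_reaction_file

ROLE_CURRENCY = "currency"
ROLE_PRIMARY = "primary"
ROLE_SECONDARY = "secondary"
SHARED = "shared"
SPECIES_SPECIFIC = "species-specific"


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-structure generator.

    Defaults are the three-species study conditions used throughout the
    test suite: 10 currency metabolites, 8 shared primary pathways of 10
    reactions each with 2 currency metabolites per reaction side, and 6
    species-specific secondary pathways of 5 reactions, each secondary
    reaction carrying a currency metabolite with probability 0.3.
    """

    n_species: int = 3
    n_currency: int = 10
    n_primary_pathways: int = 8
    primary_len: int = 10
    n_secondary_pathways_per_species: int = 6
    secondary_len: int = 5
    currency_per_reaction: int = 2
    secondary_currency_prob: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_species": self.n_species,
            "n_currency": self.n_currency,
            "n_primary_pathways": self.n_primary_pathways,
            "primary_len": self.primary_len,
            "n_secondary_pathways_per_species": self.n_secondary_pathways_per_species,
            "secondary_len": self.secondary_len,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.currency_per_reaction < 1:
            raise ValueError("currency_per_reaction must be >= 1")
        if not 0.0 <= self.secondary_currency_prob <= 1.0:
            raise ValueError("secondary_currency_prob must be in [0, 1]")
        if self.currency_per_reaction > 0 and self.n_currency < 1:
            raise ValueError("need at least one currency metabolite")


@dataclass
class SyntheticGroundTruth:
    """Planted roles and per-species reaction lists.

    ``role_of`` maps every metabolite to currency/primary/secondary;
    ``shared_of`` marks currency and primary metabolites as shared and
    secondary ones as species-specific; roles are disjoint by naming.
    """

    config: SyntheticConfig
    role_of: dict[str, str]
    shared_of: dict[str, str]
    reactions: dict[str, list[Reaction]] = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return list(self.reactions)

    def metabolites_with_role(self, role: str) -> set[str]:
        return {m for m, r in self.role_of.items() if r == role}

    @property
    def currency(self) -> set[str]:
        return self.metabolites_with_role(ROLE_CURRENCY)

    @property
    def primary(self) -> set[str]:
        return self.metabolites_with_role(ROLE_PRIMARY)

    def secondary_of(self, species: str) -> set[str]:
        prefix = f"{species}_"
        return {
            m for m, r in self.role_of.items()
            if r == ROLE_SECONDARY and m.startswith(prefix)
        }


def generate(config: SyntheticConfig) -> SyntheticGroundTruth:
    """Generate the planted multi-species reaction sets.

    Construction: (1) a currency pool shared by all species; (2) shared
    primary pathways as reaction chains M_i -> M_{i+1} with
    ``currency_per_reaction`` currency metabolites appended round-robin to
    each side; (3) per species, secondary chains anchored at a randomly
    chosen primary metabolite, each reaction carrying one randomly chosen
    currency metabolite with probability ``secondary_currency_prob``.
    Deterministic for a fixed seed.
    """
    config.validate()
    rng = random.Random(config.seed)

    currency = [f"CUR{i:02d}" for i in range(config.n_currency)]
    role_of: dict[str, str] = {c: ROLE_CURRENCY for c in currency}
    shared_of: dict[str, str] = {c: SHARED for c in currency}

    # (2) shared primary pathways with round-robin currency augmentation.
    # The currency window rotates by ONE position per reaction: substrate
    # side takes positions r..r+cpr-1, product side r+cpr..r+2cpr-1
    # (mod n_currency). Over enough reactions this links every currency
    # pair at cyclic offset 1..2cpr-1, i.e. a circulant of degree
    # 4*cpr - 2 among currency metabolites — strictly deeper than the
    # primary chains can reach, which pins the maximum core to the
    # currency pool (a stride equal to the window width would leave the
    # pool too sparse and let primary interiors into the maximum core).
    ncur, cpr = config.n_currency, config.currency_per_reaction
    shared_reactions: list[Reaction] = []
    primary_names: list[str] = []
    r = 0
    for p in range(config.n_primary_pathways):
        chain = [f"PRIM_p{p}_m{i}" for i in range(config.primary_len + 1)]
        primary_names.extend(chain)
        for i in range(config.primary_len):
            subs = {chain[i]}
            prods = {chain[i + 1]}
            if currency:
                subs |= {currency[(r + t) % ncur] for t in range(cpr)}
                prods |= {currency[(r + cpr + t) % ncur] for t in range(cpr)}
            r += 1
            shared_reactions.append(
                Reaction(
                    id=f"PRIM_p{p}_r{i}",
                    substrates=frozenset(subs),
                    products=frozenset(prods),
                )
            )
    for m in primary_names:
        role_of[m] = ROLE_PRIMARY
        shared_of[m] = SHARED

    # (3) species-specific secondary chains
    truth = SyntheticGroundTruth(config=config, role_of=role_of, shared_of=shared_of)
    for s in range(config.n_species):
        species = f"species{s}"
        rxns = list(shared_reactions)
        for p in range(config.n_secondary_pathways_per_species):
            anchor = rng.choice(primary_names) if primary_names else None
            chain = [
                f"{species}_SEC_p{p}_m{i}" for i in range(config.secondary_len)
            ]
            for m in chain:
                role_of[m] = ROLE_SECONDARY
                shared_of[m] = SPECIES_SPECIFIC
            prev = anchor
            for i, nxt in enumerate(chain):
                subs = {prev} if prev is not None else {nxt}
                prods = {nxt}
                if currency and rng.random() < config.secondary_currency_prob:
                    subs.add(rng.choice(currency))
                rxns.append(
                    Reaction(
                        id=f"{species}_SEC_p{p}_r{i}",
                        substrates=frozenset(subs),
                        products=frozenset(prods),
                    )
                )
                prev = nxt
        truth.reactions[species] = rxns
    return truth


def write_fixture(truth: SyntheticGroundTruth, directory: str | Path) -> None:
    """Write the fixture as plain text: one reaction file per species,
    role lists (currency, primary, per-species secondary — the stand-ins
    for common/secondary curated lists), and a ground-truth TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for species, rxns in truth.reactions.items():
        write_reaction_file(rxns, directory / f"{species}.reactions.txt")
    (directory / "currency.txt").write_text(
        "".join(f"{m}\n" for m in sorted(truth.currency)), encoding="utf-8"
    )
    (directory / "primary.txt").write_text(
        "".join(f"{m}\n" for m in sorted(truth.primary)), encoding="utf-8"
    )
    for species in truth.reactions:
        (directory / f"{species}.secondary.txt").write_text(
            "".join(f"{m}\n" for m in sorted(truth.secondary_of(species))),
            encoding="utf-8",
        )
    with (directory / "ground_truth.tsv").open("w", encoding="utf-8") as fh:
        fh.write("metabolite\trole\tsharing\n")
        for m in sorted(truth.role_of):
            fh.write(f"{m}\t{truth.role_of[m]}\t{truth.shared_of[m]}\n")
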