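"""Seeded synthetic MAIT cohort generator with exact ground truth.

The generator emulates the two-arm study design the analysis modules
expect: a cohort of healthy-control (HC) and Crohn's-disease (CD) donors,
each CD donor contributing paired inflamed + uninflamed colon biopsies and
each HC donor one biopsy, with single-cell paired α/β records per biopsy;
a subset of donors per cohort additionally contributes a bulk blood
β-chain repertoire. Sharing structure — public blood sequences, autologous
and allogeneic colon↔blood overlap, cross-inflammation clonotypes — is
*injected* at configured rates and recorded in a :class:`GroundTruth`
object, so downstream recovery can be checked exactly.

Design notes
------------
* β-chain CDR3 amino-acid sequences are drawn as ``C`` + 8–16 random
  residues + ``F``/``W`` from a global uniqueness registry, so two clones
  never collide by accident (collision probability < 20⁻⁸ per draw; any
  retry is counted in ``GroundTruth.collisions``). All observed sharing is
  therefore injected sharing.
* One master seed; per-donor substreams are derived through
  ``numpy.random.SeedSequence`` spawn keys, so adding a donor leaves every
  other donor's records untouched.
* Nucleotide CDR3s are back-generated from the amino-acid junction via
  uniformly chosen synonymous codons, so translation invariants hold.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from Bio.Data import CodonTable
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigError
from .models import BulkClone, CellRecord, ChainRecord, Repertoire

__all__ = ["SimConfig", "GroundTruth", "simulate_cohort", "worked_example_cohort"]

_AA20 = tuple("ACDEFGHIKLMNPQRSTVWY")

# amino acid -> sorted synonymous codons (standard table)
_CODONS: dict[str, list[str]] = {}
for _codon, _aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _CODONS.setdefault(_aa, []).append(_codon)
for _aa in _CODONS:
    _CODONS[_aa].sort()
_STOP_CODON = "TAA"

_TRBJ_GENES = ("TRBJ1-1", "TRBJ1-2", "TRBJ2-1", "TRBJ2-3", "TRBJ2-7")
_TRBD_GENES = ("TRBD1", "TRBD2")
_CONTAMINANT_TRAV = ("TRAV1-1", "TRAV8-2", "TRAV12-1", "TRAV13-1", "TRAV21")
_NONCANONICAL_TRAJ = ("TRAJ42", "TRAJ49", "TRAJ9")


class SimConfig(BaseModel):
    """Study-scale defaults: 10 donors per cohort, 8 blood samples per
    cohort, up to 80 colon cells per biopsy; blood sorts of up to 50,000
    cells are represented at 1:100 scale (500 cells) for desk runtime."""

    n_hc_donors: int = Field(default=10, ge=1)
    n_cd_donors: int = Field(default=10, ge=1)
    n_blood_per_cohort: int = Field(default=8, ge=0)
    blood_cells_per_donor: int = Field(default=500, ge=1)
    colon_cells_per_biopsy: int = Field(default=80, ge=1, le=80)
    canonical_alpha_fraction: float = Field(default=0.45, gt=0.0, lt=1.0)
    traj_weights: dict[str, float] = Field(
        default={"TRAJ33": 0.8, "TRAJ12": 0.1, "TRAJ20": 0.1}
    )
    trbv_weights: dict[str, float] = Field(
        default={
            "TRBV6-4": 0.30,
            "TRBV20-1": 0.25,
            "TRBV4-2": 0.15,
            "TRBV28": 0.15,
            "TRBV19": 0.15,
        }
    )
    clone_size_law: Literal["geometric", "zipf"] = "geometric"
    clone_size_param: float = Field(default=0.4, gt=0.0)
    public_pool_size: int = Field(default=40, ge=0)
    publicity_rates: dict[str, float] = Field(
        default={"cd_only": 0.24, "hc_only": 0.09, "shared": 0.67}
    )
    colon_blood_autologous_rate: float = Field(default=0.5, ge=0.0, le=1.0)
    colon_blood_allogeneic_rate: float = Field(default=0.13, ge=0.0, le=1.0)
    cross_inflammation_sharing_rate: float = Field(default=0.2, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_feasibility(self) -> "SimConfig":
        for name in ("traj_weights", "trbv_weights"):
            w = getattr(self, name)
            if not w or any(v < 0 for v in w.values()):
                raise ConfigError(f"{name} must be nonnegative and nonempty")
            if abs(sum(w.values()) - 1.0) > 1e-6:
                raise ConfigError(f"{name} must sum to 1")
        pr = self.publicity_rates
        if set(pr) - {"cd_only", "hc_only", "shared"} or any(
            v < 0 for v in pr.values()
        ):
            raise ConfigError(
                "publicity_rates keys must be cd_only/hc_only/shared with "
                "nonnegative weights"
            )
        if self.n_blood_per_cohort > min(self.n_hc_donors, self.n_cd_donors):
            raise ConfigError("n_blood_per_cohort exceeds donors per cohort")
        if self.clone_size_law == "geometric" and not (0 < self.clone_size_param <= 1):
            raise ConfigError("geometric clone_size_param must be in (0, 1]")
        if self.clone_size_law == "zipf" and self.clone_size_param <= 1:
            raise ConfigError("zipf clone_size_param must be > 1")
        if self.public_pool_size > 0:
            if sum(pr.values()) <= 0:
                raise ConfigError("public_pool_size > 0 needs a positive rate")
            if pr.get("cd_only", 0) > 0 and self.n_blood_per_cohort < 2:
                raise ConfigError("cd_only public sequences need >= 2 CD blood donors")
            if pr.get("hc_only", 0) > 0 and self.n_blood_per_cohort < 2:
                raise ConfigError("hc_only public sequences need >= 2 HC blood donors")
            if pr.get("shared", 0) > 0 and self.n_blood_per_cohort < 1:
                raise ConfigError("shared public sequences need blood in both cohorts")
            if self.public_pool_size > self.blood_cells_per_donor * max(
                1, 2 * self.n_blood_per_cohort
            ):
                raise ConfigError("public_pool_size larger than the clone space")
        return self


@dataclass
class GroundTruth:
    """Exact record of everything the generator injected."""

    blood_tables: dict[str, dict[str, int]] = field(default_factory=dict)
    public_pool: list[dict] = field(default_factory=list)
    autologous: set[tuple[str, str]] = field(default_factory=set)
    allogeneic: set[tuple[str, str, str]] = field(default_factory=set)
    cross_inflammation: dict[str, list[str]] = field(default_factory=dict)
    collisions: int = 0

    def expected_public(self) -> dict[str, set[str]]:
        """Public blood sequences implied by the final placements, by
        carrier-cohort class (accounts for colon↔blood injections that
        land one colonic sequence in two blood repertoires)."""
        carriers: dict[str, set[str]] = {}
        for donor, table in self.blood_tables.items():
            for aa in table:
                carriers.setdefault(aa, set()).add(donor)
        out: dict[str, set[str]] = {"cd_only": set(), "hc_only": set(), "shared": set()}
        for aa, donors in carriers.items():
            if len(donors) < 2:
                continue
            cohorts = {d[:2] for d in donors}
            if cohorts == {"CD"}:
                out["cd_only"].add(aa)
            elif cohorts == {"HC"}:
                out["hc_only"].add(aa)
            else:
                out["shared"].add(aa)
        return out

    def autologous_seqs(self) -> set[str]:
        return {aa for _, aa in self.autologous}

    def allogeneic_seqs(self) -> set[str]:
        return {aa for _, aa, _ in self.allogeneic}

    def to_json(self) -> dict:
        return {
            "blood_tables": {
                d: dict(sorted(t.items())) for d, t in sorted(self.blood_tables.items())
            },
            "public_pool": self.public_pool,
            "autologous": sorted(list(t) for t in self.autologous),
            "allogeneic": sorted(list(t) for t in self.allogeneic),
            "cross_inflammation": {
                d: sorted(v) for d, v in sorted(self.cross_inflammation.items())
            },
            "collisions": self.collisions,
        }


def _stream(seed: int, *key: str | int) -> np.random.Generator:
    """Deterministic substream: spawn_key from the master seed and a label."""
    ints = tuple(
        k if isinstance(k, int) else zlib.crc32(k.encode()) for k in key
    )
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=ints))


def _weighted(rng: np.random.Generator, weights: dict[str, float]) -> str:
    keys = sorted(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return str(keys[int(rng.choice(len(keys), p=p / p.sum()))])


def _aa_to_nt(aa: str, rng: np.random.Generator) -> str:
    out = []
    for res in aa:
        if res == "*":
            out.append(_STOP_CODON)
        else:
            codons = _CODONS[res]
            out.append(codons[int(rng.integers(len(codons)))])
    return "".join(out)


class _SeqFactory:
    """Globally unique β CDR3 amino-acid sequences (collision-checked)."""

    def __init__(self) -> None:
        self.used: set[str] = set()
        self.collisions = 0

    def fresh(self, rng: np.random.Generator) -> str:
        while True:
            core_len = int(rng.integers(8, 17))  # total length 10..18
            core = "".join(
                _AA20[int(i)] for i in rng.integers(0, 20, size=core_len)
            )
            anchor = "F" if rng.random() < 0.5 else "W"
            seq = "C" + core + anchor
            if seq in self.used:
                self.collisions += 1
                continue
            self.used.add(seq)
            return seq


def _alpha_chain(rng: np.random.Generator, cfg: SimConfig) -> ChainRecord:
    """Canonical semi-invariant alpha: TRAV1-2 joined to a weighted TRAJ;
    the junction follows the CAV[M/R]DSNYQLIW motif family (M 45%, R 30%,
    other residues 25%) at fixed length 12."""
    traj = _weighted(rng, cfg.traj_weights)
    r = rng.random()
    if r < 0.45:
        x = "M"
    elif r < 0.75:
        x = "R"
    else:
        others = [a for a in _AA20 if a not in ("M", "R")]
        x = others[int(rng.integers(len(others)))]
    aa = f"CAV{x}DSNYQLIW"
    return ChainRecord(
        locus="TRA", v_call="TRAV1-2", j_call=traj,
        cdr3_nt=_aa_to_nt(aa, rng), cdr3_aa=aa, productive=True,
    )


def _beta_chain(
    rng: np.random.Generator, cfg: SimConfig, factory: _SeqFactory
) -> ChainRecord:
    aa = factory.fresh(rng)
    return ChainRecord(
        locus="TRB",
        v_call=_weighted(rng, cfg.trbv_weights),
        d_call=_TRBD_GENES[int(rng.integers(len(_TRBD_GENES)))],
        j_call=_TRBJ_GENES[int(rng.integers(len(_TRBJ_GENES)))],
        cdr3_nt=_aa_to_nt(aa, rng),
        cdr3_aa=aa,
        productive=True,
    )


def _contaminant_alpha(rng: np.random.Generator) -> ChainRecord:
    if rng.random() < 0.7:
        # wrong V gene, otherwise productive
        v = _CONTAMINANT_TRAV[int(rng.integers(len(_CONTAMINANT_TRAV)))]
        j = _NONCANONICAL_TRAJ[int(rng.integers(len(_NONCANONICAL_TRAJ)))]
        core = "".join(_AA20[int(i)] for i in rng.integers(0, 20, size=8))
        aa = "C" + core + "F"
        return ChainRecord(
            locus="TRA", v_call=v, j_call=j,
            cdr3_nt=_aa_to_nt(aa, rng), cdr3_aa=aa, productive=True,
        )
    # nonproductive TRAV1-2 rearrangement (in-frame stop)
    core = "".join(_AA20[int(i)] for i in rng.integers(0, 20, size=4))
    aa = "CAV" + core[:2] + "*" + core[2:] + "W"
    return ChainRecord(
        locus="TRA", v_call="TRAV1-2", j_call="TRAJ33",
        cdr3_nt=_aa_to_nt(aa, rng), cdr3_aa=aa, productive=False,
    )


def _clone_size(rng: np.random.Generator, cfg: SimConfig, cap: int) -> int:
    if cfg.clone_size_law == "geometric":
        size = int(rng.geometric(cfg.clone_size_param))
    else:
        size = int(rng.zipf(cfg.clone_size_param))
    return max(1, min(size, cap))


def _blood_repertoire(
    rng: np.random.Generator, cfg: SimConfig, factory: _SeqFactory
) -> dict[tuple[str, str, str], int]:
    clones: dict[tuple[str, str, str], int] = {}
    remaining = cfg.blood_cells_per_donor
    while remaining > 0:
        size = _clone_size(rng, cfg, remaining)
        aa = factory.fresh(rng)
        v = _weighted(rng, cfg.trbv_weights)
        j = _TRBJ_GENES[int(rng.integers(len(_TRBJ_GENES)))]
        clones[(aa, v, j)] = size
        remaining -= size
    return clones


def _biopsy_cells(
    rng: np.random.Generator,
    cfg: SimConfig,
    factory: _SeqFactory,
    donor: str,
    cohort: str,
    inflammation: str,
    carryover: list[tuple[ChainRecord, ChainRecord]] | None = None,
) -> tuple[list[CellRecord], list[tuple[ChainRecord, ChainRecord]], list[str]]:
    """One biopsy: canonical clonotypes (some possibly carried over from the
    donor's other biopsy) plus contaminant cells.

    Returns (cells, canonical clonotype chain pairs, realized carryover β aa).
    """
    n = cfg.colon_cells_per_biopsy
    n_canonical = int(rng.binomial(n, cfg.canonical_alpha_fraction))
    plan: list[tuple[ChainRecord, ChainRecord, int]] = []
    realized_carryover: list[str] = []
    remaining = n_canonical
    for alpha, beta in carryover or []:
        if remaining == 0:
            break
        size = min(int(rng.geometric(0.6)), remaining)
        plan.append((alpha, beta, size))
        realized_carryover.append(beta.cdr3_aa)
        remaining -= size
    while remaining > 0:
        alpha = _alpha_chain(rng, cfg)
        beta = _beta_chain(rng, cfg, factory)
        size = _clone_size(rng, cfg, remaining)
        plan.append((alpha, beta, size))
        remaining -= size
    cells: list[CellRecord] = []
    pairs: list[tuple[ChainRecord, ChainRecord]] = []
    idx = 0
    tag = {"inflamed": "IC", "uninflamed": "NC"}[inflammation]
    for alpha, beta, size in plan:
        pairs.append((alpha, beta))
        for _ in range(size):
            cells.append(
                CellRecord(
                    cell_id=f"{donor}_{tag}_{idx:03d}",
                    donor_id=donor, cohort=cohort, tissue="colon",
                    inflammation=inflammation, alpha=alpha, beta=beta,
                )
            )
            idx += 1
    for _ in range(n - n_canonical):
        cells.append(
            CellRecord(
                cell_id=f"{donor}_{tag}_{idx:03d}",
                donor_id=donor, cohort=cohort, tissue="colon",
                inflammation=inflammation,
                alpha=_contaminant_alpha(rng),
                beta=_beta_chain(rng, cfg, factory),
            )
        )
        idx += 1
    return cells, pairs, realized_carryover


def simulate_cohort(
    config: SimConfig,
) -> tuple[list[CellRecord], list[Repertoire], GroundTruth]:
    """Generate a full synthetic cohort; deterministic for a fixed seed."""
    cfg = config
    seed = cfg.seed
    hc_ids = [f"HC{i + 1:02d}" for i in range(cfg.n_hc_donors)]
    cd_ids = [f"CD{i + 1:02d}" for i in range(cfg.n_cd_donors)]
    hc_blood = hc_ids[: cfg.n_blood_per_cohort]
    cd_blood = cd_ids[: cfg.n_blood_per_cohort]
    blood_donors = hc_blood + cd_blood
    factory = _SeqFactory()
    truth = GroundTruth()

    # 1. base blood repertoires, one substream per donor
    blood_clones: dict[str, dict[tuple[str, str, str], int]] = {}
    for cohort, ids in (("HC", hc_blood), ("CD", cd_blood)):
        for i, donor in enumerate(ids):
            rng = _stream(seed, "blood", cohort, i)
            blood_clones[donor] = _blood_repertoire(rng, cfg, factory)

    # 2. public blood pool
    g = _stream(seed, "public")
    for _ in range(cfg.public_pool_size):
        cls = _weighted(g, cfg.publicity_rates)
        n_carriers = 2 + (1 if g.random() < 0.2 else 0)
        if cls == "cd_only":
            pool = cd_blood
        elif cls == "hc_only":
            pool = hc_blood
        else:
            pool = blood_donors
        n_carriers = min(n_carriers, len(pool))
        while True:
            picked = sorted(
                np.array(pool)[g.choice(len(pool), size=n_carriers, replace=False)]
            )
            cohorts = {d[:2] for d in picked}
            if cls != "shared" or cohorts == {"HC", "CD"}:
                break
        aa = factory.fresh(g)
        v = _weighted(g, cfg.trbv_weights)
        j = _TRBJ_GENES[int(g.integers(len(_TRBJ_GENES)))]
        for donor in picked:
            blood_clones[donor][(aa, v, j)] = int(g.geometric(0.5))
        truth.public_pool.append(
            {"seq": aa, "carriers": list(picked), "class": cls}
        )

    # 3. colon biopsies, one substream per donor
    cells: list[CellRecord] = []
    colon_beta_by_donor: dict[str, list[str]] = {}
    colon_beta_chain: dict[tuple[str, str], tuple[str, str]] = {}
    for cohort, ids in (("HC", hc_ids), ("CD", cd_ids)):
        for i, donor in enumerate(ids):
            rng = _stream(seed, "colon", cohort, i)
            nc_cells, nc_pairs, _ = _biopsy_cells(
                rng, cfg, factory, donor, cohort, "uninflamed"
            )
            cells.extend(nc_cells)
            pairs = list(nc_pairs)
            if cohort == "CD":
                carry = [
                    p for p in nc_pairs
                    if rng.random() < cfg.cross_inflammation_sharing_rate
                ]
                ic_cells, ic_pairs, realized = _biopsy_cells(
                    rng, cfg, factory, donor, cohort, "inflamed",
                    carryover=carry,
                )
                cells.extend(ic_cells)
                realized_set = set(realized)
                pairs.extend(
                    p for p in ic_pairs if p[1].cdr3_aa not in realized_set
                )
                if realized:
                    truth.cross_inflammation[donor] = sorted(realized)
            seen: list[str] = []
            for alpha, beta in pairs:
                if beta.cdr3_aa not in seen:
                    seen.append(beta.cdr3_aa)
                    colon_beta_chain[(donor, beta.cdr3_aa)] = (
                        beta.v_call, beta.j_call,
                    )
            colon_beta_by_donor[donor] = seen

    # 4. colon<->blood sharing injections
    inj = _stream(seed, "inject")
    for donor in hc_ids + cd_ids:
        for aa in colon_beta_by_donor.get(donor, []):
            v, j = colon_beta_chain[(donor, aa)]
            if donor in blood_clones and inj.random() < cfg.colon_blood_autologous_rate:
                blood_clones[donor][(aa, v, j)] = int(inj.geometric(0.7))
                truth.autologous.add((donor, aa))
            if inj.random() < cfg.colon_blood_allogeneic_rate:
                others = [d for d in blood_donors if d != donor]
                if others:
                    target = others[int(inj.integers(len(others)))]
                    blood_clones[target][(aa, v, j)] = int(inj.geometric(0.7))
                    truth.allogeneic.add((donor, aa, target))

    # 5. materialize repertoires + truth tables
    blood: list[Repertoire] = []
    for donor in blood_donors:
        table = blood_clones[donor]
        clones = [
            BulkClone(cdr3_aa=k[0], v_call=k[1], j_call=k[2], count=n)
            for k, n in sorted(table.items())
        ]
        blood.append(
            Repertoire(
                donor_id=donor, cohort=donor[:2], clones=clones, tissue="blood"
            )
        )
        aa_table: dict[str, int] = {}
        for (aa, _, _), n in table.items():
            aa_table[aa] = aa_table.get(aa, 0) + n
        truth.blood_tables[donor] = aa_table
    truth.collisions = factory.collisions
    return cells, blood, truth


def worked_example_cohort() -> tuple[list[CellRecord], list[Repertoire], dict]:
    """A tiny fixed cohort whose statistics are hand-computable.

    Two donors: HC01 (one biopsy + blood) and CD01 (paired NC/IC biopsies
    + blood). All numbers below are exhaustively enumerable by hand and
    frozen in the returned ``expected`` dict:

    Blood HC01: clone counts {A:2, B:1, C:1}, N=4
        Simpson = (2·1)/(4·3) = 1/6
    Blood CD01: clone counts {A:1, D:3}, N=4
        Simpson = (3·2)/(4·3) = 1/2
    Morisita–Horn(HC01, CD01): p=(A:.5,B:.25,C:.25), q=(A:.25,D:.75)
        = 2(.5·.25) / (.375 + .625) = 0.25
    Public partition: A in both donors → 1 public, class shared.
    Colon: HC01 {B, E} (B autologous), CD01 NC {A, F}, IC {A, G}
        (A is the cross-inflammation clonotype; A sits in both bloods →
        autologous + allogeneic). Overlap rows (total, both, auto, allo):
        HC 2/1/1/0; CD all 3/1/1/1; CD NC 2/1/1/1; CD IC 2/1/1/1;
        total 5/2/2/1.
    Sharing edges: one within_HC_biopsy (B clone, 2 cells), one
        CD_cross_inflammation (A clone, NC+IC cells).
    """
    fixed = np.random.default_rng(0)  # only for codon choice; sequences fixed

    def chain(locus: str, v: str, j: str, aa: str, d: str = "") -> ChainRecord:
        return ChainRecord(
            locus=locus, v_call=v, j_call=j, d_call=d,
            cdr3_nt=_aa_to_nt(aa, fixed), cdr3_aa=aa, productive=True,
        )

    seq_a = "CASSLSGSAETQYF"
    seq_b = "CASSPGQGAYEQYF"
    seq_c = "CASSFDRGNTGELFF"
    seq_d = "CASSQDLNTEAFF"
    seq_e = "CASREGQGANVLTF"
    seq_f = "CASSYSDRGNQPQHF"
    seq_g = "CASSPTSGGYNEQFF"

    alpha_hc = chain("TRA", "TRAV1-2", "TRAJ33", "CAVMDSNYQLIW")
    alpha_hc2 = chain("TRA", "TRAV1-2", "TRAJ20", "CAVRDSNYQLIW")
    alpha_cd_a = chain("TRA", "TRAV1-2", "TRAJ33", "CAVMDSNYQLIW")
    alpha_cd_f = chain("TRA", "TRAV1-2", "TRAJ33", "CAVRDSNYQLIW")
    alpha_cd_g = chain("TRA", "TRAV1-2", "TRAJ12", "CAVMDSNYQLIW")

    beta_b = chain("TRB", "TRBV6-4", "TRBJ2-1", seq_b, d="TRBD1")
    beta_e = chain("TRB", "TRBV20-1", "TRBJ1-1", seq_e, d="TRBD2")
    beta_a = chain("TRB", "TRBV6-4", "TRBJ2-7", seq_a, d="TRBD1")
    beta_f = chain("TRB", "TRBV28", "TRBJ1-2", seq_f, d="TRBD2")
    beta_g = chain("TRB", "TRBV19", "TRBJ2-3", seq_g, d="TRBD1")
    # contaminants: wrong TRAV / nonproductive alpha
    alpha_bad_v = chain("TRA", "TRAV8-2", "TRAJ42", "CAFSGGYNKLIF")
    alpha_stop = ChainRecord(
        locus="TRA", v_call="TRAV1-2", j_call="TRAJ33",
        cdr3_nt=_aa_to_nt("CAV*NYQLIW", fixed), cdr3_aa="CAV*NYQLIW",
        productive=False,
    )

    def cell(cid, donor, cohort, infl, alpha, beta):
        return CellRecord(
            cell_id=cid, donor_id=donor, cohort=cohort, tissue="colon",
            inflammation=infl, alpha=alpha, beta=beta,
        )

    cells = [
        cell("HC01_NC_000", "HC01", "HC", "uninflamed", alpha_hc, beta_b),
        cell("HC01_NC_001", "HC01", "HC", "uninflamed", alpha_hc, beta_b),
        cell("HC01_NC_002", "HC01", "HC", "uninflamed", alpha_hc2, beta_e),
        cell("HC01_NC_003", "HC01", "HC", "uninflamed", alpha_bad_v, beta_e),
        cell("CD01_NC_000", "CD01", "CD", "uninflamed", alpha_cd_a, beta_a),
        cell("CD01_NC_001", "CD01", "CD", "uninflamed", alpha_cd_f, beta_f),
        cell("CD01_IC_000", "CD01", "CD", "inflamed", alpha_cd_a, beta_a),
        cell("CD01_IC_001", "CD01", "CD", "inflamed", alpha_cd_g, beta_g),
        cell("CD01_IC_002", "CD01", "CD", "inflamed", alpha_stop, beta_g),
    ]
    blood = [
        Repertoire(
            donor_id="HC01", cohort="HC", tissue="blood",
            clones=[  # kept sorted by CDR3 so reader round trips preserve order
                BulkClone(seq_c, 1, "TRBV19", "TRBJ1-1"),
                BulkClone(seq_a, 2, "TRBV6-4", "TRBJ2-7"),
                BulkClone(seq_b, 1, "TRBV6-4", "TRBJ2-1"),
            ],
        ),
        Repertoire(
            donor_id="CD01", cohort="CD", tissue="blood",
            clones=[
                BulkClone(seq_a, 1, "TRBV6-4", "TRBJ2-7"),
                BulkClone(seq_d, 3, "TRBV28", "TRBJ1-2"),
            ],
        ),
    ]
    expected = {
        "simpson": {"HC01": 1.0 / 6.0, "CD01": 0.5},
        "morisita_hc_cd": 0.25,
        "public": {"n_public": 1, "cd_only": 0, "hc_only": 0, "shared": 1},
        "overlap_rows": {
            "HC": (2, 1, 1, 0),
            "CD all": (3, 1, 1, 1),
            "CD NC": (2, 1, 1, 1),
            "CD IC": (2, 1, 1, 1),
            "total": (5, 2, 2, 1),
        },
        "n_canonical": 7,
        "edge_classes": {
            "within_HC_biopsy": 1,
            "CD_cross_inflammation": 1,
        },
    }
    return cells, blood, expected
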