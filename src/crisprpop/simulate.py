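"""Forward simulator of a hot-spring host population with CRISPR immunity.

The generator produces the inputs the analysis modules consume — per-locus
CRISPR amplicon-end FASTA, a virus pool FASTA and per-locus MLSA FASTA —
together with a complete ground-truth event log, so every upstream stage
can be tested against known history without external data.

Model. A population grows from a small number of founder lineages by
discrete binary splitting over a fixed number of steps. Each lineage
carries up to three CRISPR loci (C with the 25-nt C-family repeat, A1/A2
with the 24-nt A-family repeat). Per step and locus a lineage may:

* acquire a new spacer — a window copied from a shared virus pool,
  immediately downstream of a PAM dinucleotide on the virus, inserted at
  the leader end of the array;
* lose a contiguous internal run of spacers, run length drawn from a
  geometric law truncated at 5 with mean 2;
* lose the locus entirely (rare).

Twelve MLSA loci (6684 bp total by default) evolve by point mutation and
by gene conversion (unidirectional tract copy from a coexisting lineage).
All founders share one MLSA root, so housekeeping genotypes form a clonal
complex even when founder CRISPR arrays are unrelated — the regime where
one dominant housekeeping genotype hides several independent resistance
histories.

Emission clips each array to the leader-most and trailer-most
``end_depth`` spacers (a configurable few strains are emitted as fully
sequenced loci instead), interleaves the family repeat between spacers,
adds random flanks, and optionally writes a fragment on the minus strand.
Everything is reproducible from the seed, and :func:`replay` rebuilds all
final states from the event log alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .arrays import BUILTIN_REPEATS, revcomp
from .catalog import DEFAULT_MIN_IDENTITY, DEFAULT_MIN_OVERLAP, pair_match

__all__ = [
    "LocusSpec",
    "SimConfig",
    "GroundTruth",
    "SimulationOutput",
    "simulate_population",
    "replay",
    "summary_stats",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class LocusSpec:
    name: str
    family: str  # repeat family, "A" or "C"


@dataclass
class SimConfig:
    """Simulation parameters; defaults emulate a 39-strain hot-spring sample."""

    n_strains: int = 39
    n_founders: int = 3
    loci: tuple = (LocusSpec("C", "C"), LocusSpec("A1", "A"), LocusSpec("A2", "A"))
    root_array_length: int = 13
    n_viruses: int = 6
    n_ancient_viruses: int = 4  # no-longer-circulating pool that seeded founder arrays
    virus_length: int = 5000
    pam: str = "CC"
    spacer_length_mean: int = 39
    spacer_length_spread: int = 2
    acquisition_rate: float = 0.35  # per lineage per locus per step
    loss_rate: float = 0.06  # per lineage per locus per step
    loss_run_mean: float = 2.0
    loss_run_max: int = 5
    locus_loss_prob: float = 0.004  # per lineage per locus per step
    n_steps: int = 12
    mlsa_n_loci: int = 12
    mlsa_locus_length: int = 557  # 12 x 557 = 6684 bp
    mlsa_mutation_rate: float = 1e-5  # per site per lineage per step
    mlsa_conversion_rate: float = 0.01  # per lineage per step
    mlsa_tract_length: int = 500
    end_depth: int = 10
    n_full: int = 2  # strains whose loci are emitted fully sequenced
    flank_length: int = 25
    minus_strand_fraction: float = 0.2

    def validate(self) -> None:
        if self.n_strains < self.n_founders or self.n_founders < 1:
            raise ValueError("need 1 <= n_founders <= n_strains")
        if len(self.pam) != 2:
            raise ValueError("pam must be a dinucleotide")
        max_spacer = self.spacer_length_mean + self.spacer_length_spread
        if self.virus_length < max_spacer + len(self.pam):
            raise ValueError("virus shorter than spacer + PAM")
        for r in (self.acquisition_rate, self.loss_rate, self.locus_loss_prob,
                  self.mlsa_mutation_rate, self.mlsa_conversion_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if not 1 <= self.loss_run_mean <= self.loss_run_max:
            raise ValueError("loss_run_mean must lie in [1, loss_run_max]")
        if any(l.family not in BUILTIN_REPEATS for l in self.loci):
            raise ValueError("unknown repeat family")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["loci"] = [[l.name, l.family] for l in self.loci]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "loci" in d:
            d["loci"] = tuple(LocusSpec(*pair) for pair in d["loci"])
        return cls(**d)


def _truncated_geometric_pmf(mean: float, kmax: int) -> np.ndarray:
    """pmf over run lengths 1..kmax of a geometric truncated at kmax with given mean."""
    ks = np.arange(1, kmax + 1)
    if kmax == 1 or mean <= 1.0:
        out = np.zeros(kmax)
        out[0] = 1.0
        return out

    def mean_of(p):
        w = (1 - p) ** (ks - 1) * p
        w /= w.sum()
        return (ks * w).sum() - mean

    # mean_of is decreasing in p; bracket between near-uniform and near-degenerate
    p = brentq(mean_of, 1e-9, 1 - 1e-9)
    w = (1 - p) ** (ks - 1) * p
    return w / w.sum()


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode("ascii")


@dataclass
class GroundTruth:
    """Complete simulation history: replaying the event log from the
    founder states reproduces every strain's arrays and MLSA sequences."""

    config: dict
    seed: int
    founders: dict  # founder id (str) -> {locus: [[seq, origin], ...]}
    mlsa_root: str
    viruses: dict  # circulating virus id -> sequence
    ancient_viruses: dict  # ancient pool that seeded founder arrays
    tree: list  # [child, parent, step]; founders have parent None
    events: list  # global chronological event log
    strain_of_lineage: dict  # lineage id (str) -> strain name
    founder_of_strain: dict  # strain -> founder id (str)
    final: dict  # strain -> {"arrays": {locus: [[seq, origin],...] or None}, "mlsa": str, "locus_status": {locus: "OK"|"X"}}
    fragments: dict  # "strain|locus|end" -> {seqs, origins, strand, flank_left, flank_right, family}
    origin_seq: dict  # origin tag -> spacer sequence
    full_strains: list

    def to_json(self, **kw) -> str:
        return json.dumps(asdict(self), **kw)

    @classmethod
    def from_json(cls, s: str) -> "GroundTruth":
        return cls(**json.loads(s))

    # -- truth queries -------------------------------------------------

    def true_groups(self, locus: str) -> dict[str, str]:
        """Founder partition restricted to strains carrying the locus."""
        return {
            strain: self.founder_of_strain[strain]
            for strain, rec in self.final.items()
            if rec["locus_status"][locus] == "OK"
        }

    def fragment_origin(self, strain: str, locus: str, end: str, position: int) -> str:
        frag = self.fragments[f"{strain}|{locus}|{end}"]
        return frag["origins"][position - 1]

    def sequenced_event_carriers(self) -> dict[str, set]:
        """acquisition event origin -> strains carrying it in emitted fragments."""
        carriers: dict[str, set] = {}
        for key, frag in self.fragments.items():
            strain = key.split("|")[0]
            for org in frag["origins"]:
                if org.startswith("acq:"):
                    carriers.setdefault(org, set()).add(strain)
        return carriers

    def true_acquisition_pairs(
        self,
        min_identity: float = DEFAULT_MIN_IDENTITY,
        min_overlap: int = DEFAULT_MIN_OVERLAP,
    ) -> list[dict]:
        """Pairs of distinct acquisition events from the same virus, acquired
        by different lineages, whose spacers satisfy the match rule and are
        sequenced in different strains.

        Two events on one lineage path (evidenced by any strain carrying
        both spacers) are sequential acquisitions by a single lineage, not
        independent acquisitions by different hosts, and are not counted.
        """
        ev = {
            f"acq:{e['event_id']}": e
            for e in self.events
            if e["type"] == "acquisition"
        }
        full_carriers: dict[str, set] = {}
        for strain, rec in self.final.items():
            for arr in rec["arrays"].values():
                for _, org in arr or ():
                    full_carriers.setdefault(org, set()).add(strain)
        carriers = self.sequenced_event_carriers()
        tags = sorted(set(ev) & set(carriers))
        out = []
        for i, ta in enumerate(tags):
            for tb in tags[i + 1 :]:
                ea, eb = ev[ta], ev[tb]
                if ea["virus"] != eb["virus"]:
                    continue
                # need the pair observable between two different strains
                if carriers[ta] == carriers[tb] and len(carriers[ta]) == 1:
                    continue
                # same-lineage-path pairs are not independent acquisitions
                if full_carriers.get(ta, set()) & full_carriers.get(tb, set()):
                    continue
                if abs(ea["start"] - eb["start"]) > max(len(ea["sequence"]), len(eb["sequence"])):
                    continue  # cheap prefilter before the full matcher
                if pair_match(ea["sequence"], eb["sequence"], min_identity, min_overlap).is_match:
                    out.append(
                        {
                            "events": (ta, tb),
                            "virus": ea["virus"],
                            "sequences": (ea["sequence"], eb["sequence"]),
                        }
                    )
        return out


@dataclass
class SimulationOutput:
    crispr_fasta: str
    virus_fasta: str
    mlsa_fastas: dict[str, str]
    truth: GroundTruth

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "crispr_loci.fasta").write_text(self.crispr_fasta)
        (out / "viruses.fasta").write_text(self.virus_fasta)
        for locus, fasta in self.mlsa_fastas.items():
            (out / f"mlsa_{locus}.fasta").write_text(fasta)
        (out / "ground_truth.json").write_text(self.truth.to_json())


class _Lineage:
    __slots__ = ("arrays", "present", "mlsa")

    def __init__(self, arrays, present, mlsa):
        self.arrays = arrays  # {locus: list[(seq, origin)]}
        self.present = present  # {locus: bool}
        self.mlsa = mlsa  # np.uint8 array

    def clone(self) -> "_Lineage":
        return _Lineage(
            {k: list(v) for k, v in self.arrays.items()},
            dict(self.present),
            self.mlsa.copy(),
        )


def simulate_population(config: SimConfig | None = None, seed: int = 0) -> SimulationOutput:
    """Run the forward simulation and emit FASTA inputs plus ground truth."""
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    locus_names = [l.name for l in cfg.loci]
    family_of = {l.name: l.family for l in cfg.loci}

    # circulating virus pool (new acquisitions) and an ancient pool that
    # seeded the founder arrays: old spacers target elements no longer
    # sampled, so recent and ancestral spacers never collide exactly
    viruses = {f"V{i:02d}": _random_dna(rng, cfg.virus_length) for i in range(cfg.n_viruses)}
    ancient = {f"AV{i:02d}": _random_dna(rng, cfg.virus_length) for i in range(cfg.n_ancient_viruses)}
    max_sp = cfg.spacer_length_mean + cfg.spacer_length_spread

    def _sites(seq: str) -> list[int]:
        return [
            i
            for i in range(len(seq) - len(cfg.pam) - max_sp)
            if seq[i : i + len(cfg.pam)] == cfg.pam
        ]

    pam_sites = {vid: _sites(seq) for vid, seq in viruses.items()}
    ancient_sites = {vid: _sites(seq) for vid, seq in ancient.items()}
    if any(not s for s in pam_sites.values()) or any(not s for s in ancient_sites.values()):
        raise ValueError("a virus contains no usable PAM site; increase virus_length")

    # founder states: shared MLSA root, distinct root arrays per founder
    mlsa_len = cfg.mlsa_n_loci * cfg.mlsa_locus_length
    mlsa_root = _random_dna(rng, mlsa_len)
    origin_seq: dict[str, str] = {}
    founders: dict[str, dict] = {}
    lineages: dict[int, _Lineage] = {}
    founder_of_lineage: dict[int, int] = {}
    tree: list = []
    for f in range(cfg.n_founders):
        arrays = {}
        for locus in locus_names:
            arr = []
            used_sites: set[tuple[str, int]] = set()  # real arrays carry no duplicate spacers
            for i in range(cfg.root_array_length):
                length = int(
                    rng.integers(
                        cfg.spacer_length_mean - cfg.spacer_length_spread,
                        cfg.spacer_length_mean + cfg.spacer_length_spread + 1,
                    )
                )
                for _ in range(100):
                    vid = f"AV{int(rng.integers(cfg.n_ancient_viruses)):02d}"
                    site = ancient_sites[vid][int(rng.integers(len(ancient_sites[vid])))]
                    if (vid, site) not in used_sites:
                        used_sites.add((vid, site))
                        break
                else:  # pragma: no cover - tiny ancient pools only
                    raise ValueError("too few PAM sites to seed a duplicate-free root array")
                seq = ancient[vid][site + len(cfg.pam) : site + len(cfg.pam) + length]
                org = f"root:{f}:{locus}:{i}"
                origin_seq[org] = seq
                arr.append((seq, org))
            arrays[locus] = arr
        founders[str(f)] = {k: [[s, o] for s, o in v] for k, v in arrays.items()}
        lineages[f] = _Lineage(arrays, {l: True for l in locus_names},
                               np.frombuffer(mlsa_root.encode(), dtype=np.uint8).copy())
        founder_of_lineage[f] = f
        tree.append([f, None, 0])

    run_pmf = _truncated_geometric_pmf(cfg.loss_run_mean, cfg.loss_run_max)
    run_vals = np.arange(1, cfg.loss_run_max + 1)

    events: list[dict] = []
    next_id = cfg.n_founders
    acq_counter = 0
    total_splits = cfg.n_strains - cfg.n_founders
    schedule = [
        ((t + 1) * total_splits) // cfg.n_steps - (t * total_splits) // cfg.n_steps
        for t in range(cfg.n_steps)
    ]

    for step in range(cfg.n_steps):
        for _ in range(schedule[step]):
            ids = sorted(lineages)
            parent = ids[int(rng.integers(len(ids)))]
            child = next_id
            next_id += 1
            lineages[child] = lineages[parent].clone()
            founder_of_lineage[child] = founder_of_lineage[parent]
            tree.append([child, parent, step])
            events.append({"type": "split", "step": step, "parent": parent, "child": child})

        for lid in sorted(lineages):
            lin = lineages[lid]
            for locus in locus_names:
                if not lin.present[locus]:
                    continue
                if rng.random() < cfg.acquisition_rate:
                    vid = f"V{int(rng.integers(cfg.n_viruses)):02d}"
                    site = pam_sites[vid][int(rng.integers(len(pam_sites[vid])))]
                    length = int(
                        rng.integers(
                            cfg.spacer_length_mean - cfg.spacer_length_spread,
                            cfg.spacer_length_mean + cfg.spacer_length_spread + 1,
                        )
                    )
                    start = site + len(cfg.pam)
                    seq = viruses[vid][start : start + length]
                    org = f"acq:{acq_counter}"
                    origin_seq[org] = seq
                    lin.arrays[locus].insert(0, (seq, org))
                    events.append(
                        {
                            "type": "acquisition",
                            "step": step,
                            "lineage": lid,
                            "locus": locus,
                            "event_id": acq_counter,
                            "virus": vid,
                            "start": start,
                            "end": start + length,
                            "sequence": seq,
                        }
                    )
                    acq_counter += 1
                if rng.random() < cfg.loss_rate:
                    arr = lin.arrays[locus]
                    run = int(rng.choice(run_vals, p=run_pmf))
                    if len(arr) >= run + 2:
                        start_i = int(rng.integers(1, len(arr) - run))
                        lost = arr[start_i : start_i + run]
                        left, right = arr[start_i - 1], arr[start_i + run]
                        del arr[start_i : start_i + run]
                        events.append(
                            {
                                "type": "loss",
                                "step": step,
                                "lineage": lid,
                                "locus": locus,
                                "start_index": start_i,
                                "run_length": run,
                                "lost": [o for _, o in lost],
                                "left_flank": left[1],
                                "right_flank": right[1],
                            }
                        )
                if rng.random() < cfg.locus_loss_prob:
                    lin.present[locus] = False
                    lin.arrays[locus] = []
                    events.append(
                        {"type": "locus_loss", "step": step, "lineage": lid, "locus": locus}
                    )
            # MLSA point mutation
            n_mut = rng.poisson(cfg.mlsa_mutation_rate * mlsa_len)
            if n_mut:
                sites = rng.choice(mlsa_len, size=min(n_mut, mlsa_len), replace=False)
                for site in sorted(int(s) for s in sites):
                    cur = lin.mlsa[site]
                    choices = _BASES[_BASES != cur]
                    newb = int(choices[rng.integers(3)])
                    lin.mlsa[site] = newb
                    events.append(
                        {
                            "type": "mutation",
                            "step": step,
                            "lineage": lid,
                            "site": site,
                            "base": chr(newb),
                        }
                    )
            # gene conversion: copy a tract from a coexisting lineage
            if len(lineages) > 1 and rng.random() < cfg.mlsa_conversion_rate:
                others = [x for x in sorted(lineages) if x != lid]
                donor = others[int(rng.integers(len(others)))]
                start = int(rng.integers(0, mlsa_len))
                length = min(cfg.mlsa_tract_length, mlsa_len - start)
                tract = lineages[donor].mlsa[start : start + length]
                n_changed = int((lin.mlsa[start : start + length] != tract).sum())
                lin.mlsa[start : start + length] = tract
                events.append(
                    {
                        "type": "conversion",
                        "step": step,
                        "lineage": lid,
                        "donor": donor,
                        "start": start,
                        "length": length,
                        "tract": tract.tobytes().decode("ascii"),
                        "n_changed": n_changed,
                    }
                )

    # name strains in lineage-id order
    ids = sorted(lineages)
    strain_of_lineage = {lid: f"M16.{k + 1:02d}" for k, lid in enumerate(ids)}
    founder_of_strain = {
        strain_of_lineage[lid]: str(founder_of_lineage[lid]) for lid in ids
    }
    full_strains = sorted(
        rng.choice([strain_of_lineage[l] for l in ids], size=min(cfg.n_full, len(ids)), replace=False).tolist()
    )

    final: dict[str, dict] = {}
    fragments: dict[str, dict] = {}
    crispr_records: list[tuple[str, str]] = []
    for lid in ids:
        strain = strain_of_lineage[lid]
        lin = lineages[lid]
        rec = {"arrays": {}, "mlsa": lin.mlsa.tobytes().decode("ascii"), "locus_status": {}}
        for locus in locus_names:
            if not lin.present[locus]:
                rec["arrays"][locus] = None
                rec["locus_status"][locus] = "X"
                crispr_records.append((f"{strain}|{locus}|full|X", _random_dna(rng, 40)))
                continue
            arr = lin.arrays[locus]
            rec["arrays"][locus] = [[s, o] for s, o in arr]
            rec["locus_status"][locus] = "OK"
            if strain in full_strains:
                frags = [("full", arr)]
            else:
                frags = [("leader", arr[: cfg.end_depth]), ("trailer", arr[-cfg.end_depth :])]
            for end, sub in frags:
                if not sub:
                    continue
                strand = "-" if rng.random() < cfg.minus_strand_fraction else "+"
                fl = _random_dna(rng, cfg.flank_length)
                fr = _random_dna(rng, cfg.flank_length)
                fragments[f"{strain}|{locus}|{end}"] = {
                    "seqs": [s for s, _ in sub],
                    "origins": [o for _, o in sub],
                    "strand": strand,
                    "flank_left": fl,
                    "flank_right": fr,
                    "family": family_of[locus],
                }
                crispr_records.append(
                    (f"{strain}|{locus}|{end}", _render_fragment(fragments[f"{strain}|{locus}|{end}"]))
                )
        final[strain] = rec

    truth = GroundTruth(
        config=cfg.to_dict(),
        seed=seed,
        founders=founders,
        mlsa_root=mlsa_root,
        viruses=viruses,
        ancient_viruses=ancient,
        tree=tree,
        events=events,
        strain_of_lineage={str(k): v for k, v in strain_of_lineage.items()},
        founder_of_strain=founder_of_strain,
        final=final,
        fragments=fragments,
        origin_seq=origin_seq,
        full_strains=full_strains,
    )

    crispr_fasta = "".join(f">{h}\n{s}\n" for h, s in crispr_records)
    virus_fasta = "".join(f">{vid}\n{seq}\n" for vid, seq in viruses.items())
    mlsa_fastas = {}
    for k in range(cfg.mlsa_n_loci):
        locus = f"L{k + 1:02d}"
        parts = []
        for lid in ids:
            strain = strain_of_lineage[lid]
            seq = final[strain]["mlsa"][k * cfg.mlsa_locus_length : (k + 1) * cfg.mlsa_locus_length]
            parts.append(f">{strain}\n{seq}\n")
        mlsa_fastas[locus] = "".join(parts)

    return SimulationOutput(crispr_fasta, virus_fasta, mlsa_fastas, truth)


def _render_fragment(frag: dict) -> str:
    repeat = BUILTIN_REPEATS[frag["family"]].sequence
    body = repeat + "".join(s + repeat for s in frag["seqs"])
    seq = frag["flank_left"] + body + frag["flank_right"]
    return revcomp(seq) if frag["strand"] == "-" else seq


def replay(truth: GroundTruth) -> dict:
    """Deterministically rebuild final strain states from the event log.

    Returns {strain: {"arrays": ..., "mlsa": ..., "locus_status": ...}} in
    the same shape as ``truth.final``; a corrupted log surfaces as a
    mismatch against the emitted states.
    """
    cfg = SimConfig.from_dict(truth.config)
    locus_names = [l.name for l in cfg.loci]
    states: dict[int, _Lineage] = {}
    for f_str, arrays in truth.founders.items():
        f = int(f_str)
        states[f] = _Lineage(
            {loc: [(s, o) for s, o in arr] for loc, arr in arrays.items()},
            {l: True for l in locus_names},
            np.frombuffer(truth.mlsa_root.encode(), dtype=np.uint8).copy(),
        )
    for e in truth.events:
        typ = e["type"]
        if typ == "split":
            states[e["child"]] = states[e["parent"]].clone()
        elif typ == "acquisition":
            lin = states[e["lineage"]]
            lin.arrays[e["locus"]].insert(0, (e["sequence"], f"acq:{e['event_id']}"))
        elif typ == "loss":
            lin = states[e["lineage"]]
            arr = lin.arrays[e["locus"]]
            i, r = e["start_index"], e["run_length"]
            if [o for _, o in arr[i : i + r]] != list(e["lost"]):
                raise ValueError("replay mismatch: loss event does not match state")
            del arr[i : i + r]
        elif typ == "locus_loss":
            lin = states[e["lineage"]]
            lin.present[e["locus"]] = False
            lin.arrays[e["locus"]] = []
        elif typ == "mutation":
            states[e["lineage"]].mlsa[e["site"]] = ord(e["base"])
        elif typ == "conversion":
            lin = states[e["lineage"]]
            tract = np.frombuffer(e["tract"].encode(), dtype=np.uint8)
            lin.mlsa[e["start"] : e["start"] + e["length"]] = tract
        else:  # pragma: no cover - defensive
            raise ValueError(f"unknown event type {typ}")

    out = {}
    for lid_str, strain in truth.strain_of_lineage.items():
        lin = states[int(lid_str)]
        out[strain] = {
            "arrays": {
                loc: ([[s, o] for s, o in lin.arrays[loc]] if lin.present[loc] else None)
                for loc in locus_names
            },
            "mlsa": lin.mlsa.tobytes().decode("ascii"),
            "locus_status": {loc: ("OK" if lin.present[loc] else "X") for loc in locus_names},
        }
    return out


def render_crispr_fasta(truth: GroundTruth) -> list[tuple[str, str]]:
    """Re-render the sequenced fragments recorded in the ground truth."""
    return [(key, _render_fragment(frag)) for key, frag in truth.fragments.items()]


# ---------------------------------------------------------------------------
# recovery report


def _rand_index(part_a: dict, part_b: dict) -> float:
    """Pair-counting Rand index between two partitions over shared keys."""
    keys = sorted(set(part_a) & set(part_b))
    if len(keys) < 2:
        return 1.0
    agree = total = 0
    for i, x in enumerate(keys):
        for y in keys[i + 1 :]:
            same_a = part_a[x] == part_a[y]
            same_b = part_b[x] == part_b[y]
            agree += same_a == same_b
            total += 1
    return agree / total


def _loss_recovery(truth: GroundTruth, detected_losses) -> dict:
    """Match detected loss events to planted ones.

    A planted event is *recoverable* when some strain carrying the
    deletion shows both flanking spacers adjacent in one emitted fragment
    while another strain shows flanks plus the full lost run intact; the
    detected run length for such an event must equal the planted one.
    """
    frag_origins: dict[str, list[list[str]]] = {}
    for key, frag in truth.fragments.items():
        strain = key.split("|")[0]
        frag_origins.setdefault(strain, []).append([frag["origins"], key.split("|")[1]])

    def has_adjacent(strain, locus, left, right):
        for origins, loc in frag_origins.get(strain, ()):
            if loc != locus:
                continue
            for i in range(len(origins) - 1):
                if origins[i] == left and origins[i + 1] == right:
                    return True
        return False

    def has_intact(strain, locus, left, lost, right):
        window = [left, *lost, right]
        for origins, loc in frag_origins.get(strain, ()):
            if loc != locus:
                continue
            for i in range(len(origins) - len(window) + 1):
                if origins[i : i + len(window)] == window:
                    return True
        return False

    detected_index = {}
    for ev in detected_losses:
        detected_index.setdefault(
            (ev.strain, ev.locus, ev.left_flank, ev.right_flank), set()
        ).add(ev.run_length)

    recoverable = recovered = 0
    matched_runs = []
    strains = list(truth.final)
    for e in truth.events:
        if e["type"] != "loss":
            continue
        locus = e["locus"]
        lf, rf = e["left_flank"], e["right_flank"]
        carriers = [s for s in strains if has_adjacent(s, locus, lf, rf)]
        witnesses = [s for s in strains if has_intact(s, locus, lf, e["lost"], rf)]
        if not carriers or not witnesses:
            continue
        recoverable += 1
        lf_seq, rf_seq = truth.origin_seq[lf], truth.origin_seq[rf]
        hit = None
        for s in carriers:
            runs = detected_index.get((s, locus, lf_seq, rf_seq))
            if runs and e["run_length"] in runs:
                hit = e["run_length"]
                break
        if hit is not None:
            recovered += 1
            matched_runs.append(hit)
    return {
        "recoverable": recoverable,
        "recovered": recovered,
        "recall": recovered / recoverable if recoverable else float("nan"),
        "matched_run_lengths": matched_runs,
        "mean_matched_run": float(np.mean(matched_runs)) if matched_runs else float("nan"),
    }


def _acquisition_recovery(truth: GroundTruth, pairs) -> dict:
    """Precision/recall of acquisition classification against planted events."""

    def origin_of(spacer):
        key = f"{spacer.strain}|{spacer.locus}|{spacer.end}"
        return truth.fragments[key]["origins"][spacer.position - 1]

    detected = [p for p in pairs if not p.excluded]
    false_pos = 0
    detected_event_pairs = set()
    ll = 0
    for p in detected:
        oa, ob = origin_of(p.spacer_a), origin_of(p.spacer_b)
        if oa == ob:
            false_pos += 1  # the very same planted spacer called an acquisition
            continue
        if oa.startswith("acq:") and ob.startswith("acq:"):
            detected_event_pairs.add(frozenset((oa, ob)))
        if p.end_class == "leader-leader":
            ll += 1
    true_pairs = truth.true_acquisition_pairs()
    true_sets = {frozenset(t["events"]) for t in true_pairs}
    recovered = len(true_sets & detected_event_pairs)
    return {
        "n_detected": len(detected),
        "false_ancestral": false_pos,
        "precision": 1.0 - (false_pos / len(detected)) if detected else 1.0,
        "n_true": len(true_sets),
        "recovered": recovered,
        "recall": recovered / len(true_sets) if true_sets else float("nan"),
        "leader_leader_fraction": ll / len(detected) if detected else float("nan"),
    }


def summary_stats(truth: GroundTruth, detected_losses, groups_by_locus, pairs) -> dict:
    """Recovery report: detected losses, ancestry partitions and acquisition
    pairs scored against the simulation's ground truth."""
    group_rand = {}
    for locus, groups in groups_by_locus.items():
        det = {s: g.group_id for g in groups for s in g.members}
        group_rand[locus] = _rand_index(det, truth.true_groups(locus))
    return {
        "losses": _loss_recovery(truth, detected_losses),
        "groups_rand_index": group_rand,
        "acquisitions": _acquisition_recovery(truth, pairs),
    }
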