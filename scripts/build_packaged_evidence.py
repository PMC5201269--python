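"""One-time builder for the packaged 97-gene catalog + evidence mirror.

Constructs gene-level flags satisfying the mirror's reference counts:
|occ>=1| = 62, |enr>=1| = 46, |req>=1| = 24, |enr & req| = 17,
|occ & (enr|req)| = 39 (muscle union 53), and the named exemplars
(daf-21/unc-45 in all three occupancy sets, hsp-12.2 in two, hsp-17/fkb-6
in none, etc.). Output is frozen into src/chapnet/data/.
"""

from pathlib import Path

OUT = Path(__file__).resolve().parents[1] / "src" / "chapnet" / "data"

# ---- catalog: 97 genes ----------------------------------------------------
FAMILIES = {
    "Hsp60/10": [
        "hsp-60", "hsp-10", "cct-1", "cct-2", "cct-3", "cct-4", "cct-5",
        "cct-6", "cct-7", "cct-8",
    ],
    "Hsp70": [
        "hsp-1", "hsp-3", "hsp-4", "hsp-6", "hsp-70", "f44e5.4", "f44e5.5",
        "c12c8.1", "f11f1.1", "stc-1", "t14g8.3", "c30c11.4", "hsp-110",
    ],
    "Hsp40/NEF": [
        *[f"dnj-{i}" for i in range(1, 31)],
        "rme-8", "unc-23", "t05c3.5", "y73b6bl.12", "f39b2.10", "c08h9.14",
    ],
    "Hsp90/cochaperone": [
        "daf-21", "sti-1", "c01g10.8", "cdc-37", "pph-5", "fkb-6", "unc-45",
        "chn-1", "r05f9.10", "sgt-1", "tah-1", "ppt-1", "aip-1",
    ],
    "sHsp": [
        "hsp-12.1", "hsp-12.2", "hsp-12.3", "hsp-12.6", "hsp-16.1",
        "hsp-16.2", "hsp-16.11", "hsp-16.41", "hsp-16.48", "hsp-16.49",
        "hsp-17", "hsp-25", "hsp-43", "sip-1", "f08h9.3", "f08h9.4",
    ],
    "other": [
        "pfd-1", "pfd-2", "pfd-3", "pfd-4", "pfd-5", "pfd-6", "nud-1",
        "c17g10.2", "b0035.14",
    ],
}
catalog = [(g, fam) for fam, genes in FAMILIES.items() for g in genes]
genes = [g for g, _ in catalog]
assert len(genes) == 97, len(genes)
assert len(set(genes)) == 97

# ---- region assignment ----------------------------------------------------
# A = occupancy, E = enriched, R = required. Region sizes (sum 97):
#   AER 13, AE 20, AR 6, A-only 23, ER 4, E-only 9, R-only 1, outside 21
AER = ["unc-45", "cct-2", "cct-5", "cct-7", "sip-1", "hsp-12.1", "dnj-24",
       "unc-23", "hsp-1", "hsp-16.41", "dnj-12", "dnj-13", "stc-1"]
AE = ["hsp-12.2"]
AR = ["daf-21", "cct-1", "cct-3", "cct-4", "cct-6", "cct-8"]
ER = ["c01g10.8", "hsp-12.3", "f08h9.3", "dnj-5"]
R_ONLY = ["hsp-25"]
OUTSIDE_FORCED = ["hsp-17", "fkb-6", "dnj-2"]

assert len(AER) == 13 and len(AR) == 6 and len(ER) == 4 and len(R_ONLY) == 1

reserved = set(AER + AE + AR + ER + R_ONLY + OUTSIDE_FORCED)
pool = [g for g in genes if g not in reserved]
# fill remaining regions deterministically from the catalog order
need_AE = 20 - len(AE)
need_Aonly = 23
need_Eonly = 9
AE += pool[:need_AE]
A_ONLY = pool[need_AE : need_AE + need_Aonly]
E_ONLY = pool[need_AE + need_Aonly : need_AE + need_Aonly + need_Eonly]
OUTSIDE = OUTSIDE_FORCED + pool[need_AE + need_Aonly + need_Eonly :]

A = set(AER + AE + AR + A_ONLY)
E = set(AER + AE + ER + E_ONLY)
R = set(AER + AR + ER + R_ONLY)
assert len(A) == 62, len(A)
assert len(E) == 46, len(E)
assert len(R) == 24, len(R)
assert len(E & R) == 17
assert len(A & (E | R)) == 39
assert len(E | R) == 53
assert len(A | E | R | set(OUTSIDE)) == 97 and len(set(OUTSIDE) & (A | E | R)) == 0

# ---- per-category experiment membership -----------------------------------
OCC_COLS = ["chipseq_peaks", "rnai_union", "rnai_overlap"]
ENR_COLS = ["myoconv_rnaseq", "embryo_muscle_microarray", "l1_muscle_mrna"]
REQ_COLS = ["folding_function", "myopathy_motility", "sarcomere_localization"]

FIXED_RANKS = {
    # occupancy ranks pinned for the named exemplar genes
    "occ": {"daf-21": 3, "unc-45": 3, "hsp-12.2": 2},
    # required criteria for exemplars
    "req": {
        "unc-45": 3,          # function + phenotype + localization
        "daf-21": 1,          # myosin folding function
        "unc-23": 1,          # motility phenotype
        "hsp-12.1": 1,        # sarcomere localization
        "dnj-24": 1,          # myopathy
        **{f"cct-{i}": 1 for i in range(1, 9)},  # actin folding function
    },
}

def assign(members, cols, fixed, offset):
    """Deterministic rank + column assignment: rank cycles 1,2,3 unless fixed."""
    flags = {g: {c: 0 for c in cols} for g in genes}
    for i, g in enumerate(sorted(members)):
        r = fixed.get(g, (i % 3) + 1)
        start = (i + offset) % 3
        for j in range(r):
            flags[g][cols[(start + j) % 3]] = 1
    return flags

occ_flags = assign(A, OCC_COLS, FIXED_RANKS["occ"], 0)
enr_flags = assign(E, ENR_COLS, {}, 1)
req_flags = assign(R, REQ_COLS, FIXED_RANKS["req"], 2)
# pin exemplar criterion columns
for g in list(FIXED_RANKS["req"]):
    req_flags[g] = {c: 0 for c in REQ_COLS}
req_flags["unc-45"] = {c: 1 for c in REQ_COLS}
req_flags["daf-21"]["folding_function"] = 1
req_flags["unc-23"]["myopathy_motility"] = 1
req_flags["hsp-12.1"]["sarcomere_localization"] = 1
req_flags["dnj-24"]["myopathy_motility"] = 1
for i in range(1, 9):
    req_flags[f"cct-{i}"]["folding_function"] = 1

OUT.mkdir(parents=True, exist_ok=True)
with (OUT / "catalog.tsv").open("w") as fh:
    fh.write("gene_id\tfamily\n")
    for g, fam in catalog:
        fh.write(f"{g}\t{fam}\n")

for fname, cols, flags in [
    ("evidence_occupancy.tsv", OCC_COLS, occ_flags),
    ("evidence_enrichment.tsv", ENR_COLS, enr_flags),
    ("evidence_required.tsv", REQ_COLS, req_flags),
]:
    with (OUT / fname).open("w") as fh:
        fh.write("gene_id\t" + "\t".join(cols) + "\n")
        for g in genes:
            fh.write(g + "\t" + "\t".join(str(flags[g][c]) for c in cols) + "\n")

print("wrote packaged data to", OUT)
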