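"""Optional, network-requiring checks against deposited GenBank records.

Downloads the deposited passenger pigeon assemblies (KC489473, KC489474),
the third passenger pigeon mitogenome (JQ692598), and the rock pigeon
reference (GU908131), then recomputes record lengths, N counts, base
composition, and multi-genome segregating sites with this package.

This script is NOT part of the test suite: it needs internet access and
NCBI availability.  Run it manually when online:

    python scripts/fetch_deposited_checks.py --email you@example.org
"""

from __future__ import annotations

import argparse

from Bio import Entrez, SeqIO

from paleomito.compare import composition, multi_compare
from paleomito.io import Region, SequenceRecord

ACCESSIONS = ["KC489473", "KC489474", "JQ692598", "GU908131"]
EXCLUDED_REGIONS = ("16S ribosomal RNA", "ND6", "D-loop")


def fetch(accession: str) -> tuple[SequenceRecord, list[Region]]:
    handle = Entrez.efetch(db="nucleotide", id=accession, rettype="gb", retmode="text")
    rec = SeqIO.read(handle, "genbank")
    regions = []
    for feat in rec.features:
        if feat.type not in {"CDS", "tRNA", "rRNA", "D-loop"}:
            continue
        name = (
            feat.qualifiers.get("gene", [None])[0]
            or feat.qualifiers.get("product", [None])[0]
            or feat.type
        )
        regions.append(
            Region(
                name,
                int(feat.location.start),
                int(feat.location.end),
                "-" if feat.location.strand == -1 else "+",
                {"D-loop": "control_region"}.get(feat.type, feat.type),
            )
        )
    return SequenceRecord(accession, str(rec.seq).upper()), regions


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", required=True, help="NCBI Entrez contact email")
    args = parser.parse_args()
    Entrez.email = args.email

    genomes = {}
    annotations = {}
    for acc in ACCESSIONS:
        genomes[acc], annotations[acc] = fetch(acc)
        seq = genomes[acc]
        fracs, n_count = composition(seq.bases)
        comp = ", ".join(f"{b}:{fracs[b]:.2f}" for b in "GATC")
        print(f"{acc}: {len(seq)} bp, {n_count} Ns, composition {comp}")

    pigeons = [genomes[a] for a in ("KC489473", "KC489474", "JQ692598")]
    res = multi_compare(
        pigeons, annotations["KC489473"], exclude_regions=EXCLUDED_REGIONS
    )
    print(
        f"segregating sites among the three passenger pigeon mitogenomes "
        f"(excluding 16S rRNA, ND6, control region): {res.segregating_sites} "
        f"({res.nonsynonymous_sites} nonsynonymous)"
    )


if __name__ == "__main__":
    main()
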