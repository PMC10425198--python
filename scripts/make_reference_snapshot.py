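"""Regenerate the packaged synthetic reference snapshot.

The packaged KO->KEGG-pathway membership map and the KO/EC/MetaCyc
annotation tables are *synthetic* stand-ins for a real KEGG/MetaCyc
snapshot: pathway identifiers, names and classes follow the KEGG naming
conventions, but the KO memberships and ortholog descriptions are drawn
deterministically from a seeded generator.  Real KEGG content cannot be
redistributed here and drifts over time; a pinned synthetic snapshot keeps
every downstream test hermetic and reproducible.

Run from the repository root:

    python scripts/make_reference_snapshot.py
"""

from __future__ import annotations

import pathlib

import numpy as np

OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "picoda" / "data"

SNAPSHOT_VERSION = "synthetic-snapshot-1.0"
SEED = 20230801

# (id, name, top-level class; subclass) — identifiers and names follow KEGG
# conventions so that namespace inference and annotation joins behave as
# they would on real exports; memberships below are synthetic.
PATHWAYS = [
    ("ko00010", "Glycolysis / Gluconeogenesis", "Metabolism; Carbohydrate metabolism"),
    ("ko00020", "Citrate cycle (TCA cycle)", "Metabolism; Carbohydrate metabolism"),
    ("ko00030", "Pentose phosphate pathway", "Metabolism; Carbohydrate metabolism"),
    ("ko00040", "Pentose and glucuronate interconversions", "Metabolism; Carbohydrate metabolism"),
    ("ko00051", "Fructose and mannose metabolism", "Metabolism; Carbohydrate metabolism"),
    ("ko00052", "Galactose metabolism", "Metabolism; Carbohydrate metabolism"),
    ("ko00061", "Fatty acid biosynthesis", "Metabolism; Lipid metabolism"),
    ("ko00071", "Fatty acid degradation", "Metabolism; Lipid metabolism"),
    ("ko00100", "Steroid biosynthesis", "Metabolism; Lipid metabolism"),
    ("ko00190", "Oxidative phosphorylation", "Metabolism; Energy metabolism"),
    ("ko00220", "Arginine biosynthesis", "Metabolism; Amino acid metabolism"),
    ("ko00230", "Purine metabolism", "Metabolism; Nucleotide metabolism"),
    ("ko00240", "Pyrimidine metabolism", "Metabolism; Nucleotide metabolism"),
    ("ko00250", "Alanine, aspartate and glutamate metabolism", "Metabolism; Amino acid metabolism"),
    ("ko00260", "Glycine, serine and threonine metabolism", "Metabolism; Amino acid metabolism"),
    ("ko00270", "Cysteine and methionine metabolism", "Metabolism; Amino acid metabolism"),
    ("ko00280", "Valine, leucine and isoleucine degradation", "Metabolism; Amino acid metabolism"),
    ("ko00290", "Valine, leucine and isoleucine biosynthesis", "Metabolism; Amino acid metabolism"),
    ("ko00300", "Lysine biosynthesis", "Metabolism; Amino acid metabolism"),
    ("ko00330", "Arginine and proline metabolism", "Metabolism; Amino acid metabolism"),
    ("ko00340", "Histidine metabolism", "Metabolism; Amino acid metabolism"),
    ("ko00350", "Tyrosine metabolism", "Metabolism; Amino acid metabolism"),
    ("ko00360", "Phenylalanine metabolism", "Metabolism; Amino acid metabolism"),
    ("ko00400", "Phenylalanine, tyrosine and tryptophan biosynthesis", "Metabolism; Amino acid metabolism"),
    ("ko00500", "Starch and sucrose metabolism", "Metabolism; Carbohydrate metabolism"),
    ("ko00520", "Amino sugar and nucleotide sugar metabolism", "Metabolism; Carbohydrate metabolism"),
    ("ko00550", "Peptidoglycan biosynthesis", "Metabolism; Glycan biosynthesis and metabolism"),
    ("ko00561", "Glycerolipid metabolism", "Metabolism; Lipid metabolism"),
    ("ko00562", "Inositol phosphate metabolism", "Metabolism; Carbohydrate metabolism"),
    ("ko00620", "Pyruvate metabolism", "Metabolism; Carbohydrate metabolism"),
    ("ko00630", "Glyoxylate and dicarboxylate metabolism", "Metabolism; Carbohydrate metabolism"),
    ("ko00640", "Propanoate metabolism", "Metabolism; Carbohydrate metabolism"),
    ("ko00650", "Butanoate metabolism", "Metabolism; Carbohydrate metabolism"),
    ("ko00680", "Methane metabolism", "Metabolism; Energy metabolism"),
    ("ko00710", "Carbon fixation in photosynthetic organisms", "Metabolism; Energy metabolism"),
    ("ko00720", "Carbon fixation pathways in prokaryotes", "Metabolism; Energy metabolism"),
    ("ko00730", "Thiamine metabolism", "Metabolism; Metabolism of cofactors and vitamins"),
    ("ko00740", "Riboflavin metabolism", "Metabolism; Metabolism of cofactors and vitamins"),
    ("ko00750", "Vitamin B6 metabolism", "Metabolism; Metabolism of cofactors and vitamins"),
    ("ko00760", "Nicotinate and nicotinamide metabolism", "Metabolism; Metabolism of cofactors and vitamins"),
    ("ko00770", "Pantothenate and CoA biosynthesis", "Metabolism; Metabolism of cofactors and vitamins"),
    ("ko00780", "Biotin metabolism", "Metabolism; Metabolism of cofactors and vitamins"),
    ("ko00790", "Folate biosynthesis", "Metabolism; Metabolism of cofactors and vitamins"),
    ("ko00860", "Porphyrin and chlorophyll metabolism", "Metabolism; Metabolism of cofactors and vitamins"),
    ("ko00900", "Terpenoid backbone biosynthesis", "Metabolism; Metabolism of terpenoids and polyketides"),
    ("ko00910", "Nitrogen metabolism", "Metabolism; Energy metabolism"),
    ("ko00920", "Sulfur metabolism", "Metabolism; Energy metabolism"),
    ("ko00970", "Aminoacyl-tRNA biosynthesis", "Genetic Information Processing; Translation"),
    ("ko02010", "ABC transporters", "Environmental Information Processing; Membrane transport"),
    ("ko02020", "Two-component system", "Environmental Information Processing; Signal transduction"),
    ("ko02024", "Quorum sensing", "Cellular Processes; Cellular community - prokaryotes"),
    ("ko02030", "Bacterial chemotaxis", "Cellular Processes; Cell motility"),
    ("ko02040", "Flagellar assembly", "Cellular Processes; Cell motility"),
    ("ko02060", "Phosphotransferase system (PTS)", "Environmental Information Processing; Membrane transport"),
    ("ko03010", "Ribosome", "Genetic Information Processing; Translation"),
    ("ko03018", "RNA degradation", "Genetic Information Processing; Folding, sorting and degradation"),
    ("ko03020", "RNA polymerase", "Genetic Information Processing; Transcription"),
    ("ko03030", "DNA replication", "Genetic Information Processing; Replication and repair"),
    ("ko03060", "Protein export", "Genetic Information Processing; Folding, sorting and degradation"),
    ("ko03070", "Bacterial secretion system", "Environmental Information Processing; Membrane transport"),
    ("ko03410", "Base excision repair", "Genetic Information Processing; Replication and repair"),
    ("ko03420", "Nucleotide excision repair", "Genetic Information Processing; Replication and repair"),
    ("ko03430", "Mismatch repair", "Genetic Information Processing; Replication and repair"),
    ("ko03440", "Homologous recombination", "Genetic Information Processing; Replication and repair"),
    ("ko04122", "Sulfur relay system", "Genetic Information Processing; Folding, sorting and degradation"),
    ("ko05010", "Alzheimer disease", "Human Diseases; Neurodegenerative disease"),
    ("ko05012", "Parkinson disease", "Human Diseases; Neurodegenerative disease"),
    ("ko05016", "Huntington disease", "Human Diseases; Neurodegenerative disease"),
]

ENZYME_WORDS = [
    "dehydrogenase", "kinase", "synthase", "reductase", "transferase",
    "hydrolase", "ligase", "isomerase", "mutase", "carboxylase",
    "phosphatase", "epimerase", "aldolase", "permease", "oxidase",
    "transporter", "racemase", "decarboxylase", "aminotransferase",
    "thioesterase",
]
SUBSTRATE_WORDS = [
    "glucose", "pyruvate", "acetyl-CoA", "glutamate", "succinate",
    "ribose", "malate", "citrate", "serine", "histidine", "NADH",
    "fructose", "xylose", "lactate", "glycerol", "alanine", "urea",
    "sulfate", "nitrate", "maltose",
]


def main() -> None:
    rng = np.random.default_rng(SEED)
    OUT.mkdir(parents=True, exist_ok=True)

    # KO universe: 900 distinct K-numbers.
    ko_numbers = rng.choice(np.arange(1, 30000), size=900, replace=False)
    ko_ids = sorted(f"K{n:05d}" for n in ko_numbers)

    # Synthetic ortholog descriptions.
    with open(OUT / "ko_info.synthetic.tsv", "w") as fh:
        fh.write(f"# ref_map_version: {SNAPSHOT_VERSION}\n")
        fh.write("id\tdescription\n")
        for ko in ko_ids:
            enz = ENZYME_WORDS[rng.integers(len(ENZYME_WORDS))]
            sub = SUBSTRATE_WORDS[rng.integers(len(SUBSTRATE_WORDS))]
            ec = f"{rng.integers(1, 7)}.{rng.integers(1, 20)}.{rng.integers(1, 20)}.{rng.integers(1, 99)}"
            fh.write(f"{ko}\t{sub} {enz} [EC:{ec}]\n")

    # Membership map: each pathway draws 15-60 member KOs.
    with open(OUT / "ko_pathway_map.synthetic.tsv", "w") as fh:
        fh.write(f"# ref_map_version: {SNAPSHOT_VERSION}\n")
        for pid, _name, _cls in PATHWAYS:
            k = int(rng.integers(15, 61))
            members = rng.choice(ko_ids, size=k, replace=False)
            for ko in sorted(members):
                fh.write(f"{pid}\t{ko}\n")

    with open(OUT / "kegg_pathway_info.synthetic.tsv", "w") as fh:
        fh.write(f"# ref_map_version: {SNAPSHOT_VERSION}\n")
        fh.write("id\tname\tdescription\tclass\tmap_link\n")
        for pid, name, cls in PATHWAYS:
            desc = f"{name} reference pathway (synthetic snapshot)"
            link = f"https://www.kegg.jp/pathway/{pid}"
            fh.write(f"{pid}\t{name}\t{desc}\t{cls}\t{link}\n")

    # EC annotation table (synthetic descriptions, EC-style identifiers).
    with open(OUT / "ec_info.synthetic.tsv", "w") as fh:
        fh.write(f"# ref_map_version: {SNAPSHOT_VERSION}\n")
        fh.write("id\tdescription\n")
        seen = set()
        while len(seen) < 80:
            ec = f"{rng.integers(1, 7)}.{rng.integers(1, 20)}.{rng.integers(1, 20)}.{rng.integers(1, 99)}"
            if ec in seen:
                continue
            seen.add(ec)
            enz = ENZYME_WORDS[rng.integers(len(ENZYME_WORDS))]
            sub = SUBSTRATE_WORDS[rng.integers(len(SUBSTRATE_WORDS))]
            fh.write(f"EC:{ec}\t{sub} {enz}\n")

    # MetaCyc annotation table (synthetic, MetaCyc-style identifiers).
    with open(OUT / "metacyc_info.synthetic.tsv", "w") as fh:
        fh.write(f"# ref_map_version: {SNAPSHOT_VERSION}\n")
        fh.write("id\tdescription\n")
        for i in range(80):
            sub = SUBSTRATE_WORDS[rng.integers(len(SUBSTRATE_WORDS))]
            kind = ["biosynthesis", "degradation", "fermentation", "oxidation"][
                rng.integers(4)
            ]
            fh.write(f"PWY-{1000 + i}\t{sub} {kind} (synthetic snapshot)\n")

    print("snapshot written to", OUT)


if __name__ == "__main__":
    main()
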