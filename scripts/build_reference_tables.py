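"""Regenerate the bundled reference tables under src/bonemsi/data/.

The metabolite list is a hand-curated, desk-scale emulation of the KEGG/HMDB
records relevant to bone metabolism: glycolysis/gluconeogenesis, the pentose
phosphate pathway, purine/pyrimidine and nucleotide-sugar metabolism, the
CDP-choline and CDP-ethanolamine (Kennedy) branches, cysteine/methionine,
galactose, inositol, arginine, ascorbate/aldarate and TCA intermediates,
free fatty acids, cofactors, plus a set of exogenous decoys (drugs,
pesticides, the 9-aminoacridine MALDI matrix) used to exercise the
exogenous-annotation filter.  Monoisotopic masses are recomputed from the
formulas at build time.

Run from the repository root:  python scripts/build_reference_tables.py
"""

from __future__ import annotations

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from bonemsi.chem import GLYCAN_RESIDUES, neutral_mass  # noqa: E402

# (id, name, formula, pathways ;-joined, chem class, endogenous)
METABOLITES = [
    # --- glycolysis / gluconeogenesis ---
    ("glc", "glucose", "C6H12O6", "glycolysis;galactose", "Carbohydrates", 1),
    ("fru", "fructose", "C6H12O6", "glycolysis;fructose_mannose", "Carbohydrates", 1),
    ("g6p", "glucose 6-phosphate", "C6H13O9P", "glycolysis;ppp;galactose", "Carbohydrates", 1),
    ("g1p", "glucose 1-phosphate", "C6H13O9P", "glycolysis;galactose;glycogen", "Carbohydrates", 1),
    ("f6p", "fructose 6-phosphate", "C6H13O9P", "glycolysis;ppp;hexosamine", "Carbohydrates", 1),
    ("fbp", "fructose 1,6-bisphosphate", "C6H14O12P2", "glycolysis", "Carbohydrates", 1),
    ("gap", "glyceraldehyde 3-phosphate", "C3H7O6P", "glycolysis;ppp", "Carbohydrates", 1),
    ("dhap", "glycerone phosphate", "C3H7O6P", "glycolysis;galactose;inositol_p", "Carbohydrates", 1),
    ("bpg", "2,3-bisphosphoglycerate", "C3H8O10P2", "glycolysis", "Carbohydrates", 1),
    ("pg3", "3-phosphoglycerate", "C3H7O7P", "glycolysis", "Carbohydrates", 1),
    ("pep", "phosphoenolpyruvate", "C3H5O6P", "glycolysis", "Carbohydrates", 1),
    ("pyr", "pyruvate", "C3H4O3", "glycolysis;cys_met", "Organic acids", 1),
    ("lac", "lactate", "C3H6O3", "glycolysis", "Organic acids", 1),
    # --- pentose phosphate pathway ---
    ("pgl", "6-phosphogluconolactone", "C6H11O9P", "ppp", "Carbohydrates", 1),
    ("pgc", "6-phosphogluconate", "C6H13O10P", "ppp", "Carbohydrates", 1),
    ("r5p", "ribose 5-phosphate", "C5H11O8P", "ppp;purine", "Carbohydrates", 1),
    ("ru5p", "ribulose 5-phosphate", "C5H11O8P", "ppp", "Carbohydrates", 1),
    ("x5p", "xylulose 5-phosphate", "C5H11O8P", "ppp", "Carbohydrates", 1),
    ("e4p", "erythrose 4-phosphate", "C4H9O7P", "ppp", "Carbohydrates", 1),
    ("s7p", "sedoheptulose 7-phosphate", "C7H15O10P", "ppp", "Carbohydrates", 1),
    ("dr5p", "deoxyribose 5-phosphate", "C5H11O7P", "ppp;pyrimidine", "Carbohydrates", 1),
    ("prpp", "phosphoribosyl pyrophosphate", "C5H13O14P3", "ppp;purine;pyrimidine", "Carbohydrates", 1),
    ("rib", "ribose", "C5H10O5", "ppp", "Carbohydrates", 1),
    # --- phosphates ---
    ("ppi", "pyrophosphate", "H4P2O7", "oxidative_phosphorylation", "Inorganic acids", 1),
    ("pi", "phosphate", "H3PO4", "oxidative_phosphorylation", "Inorganic acids", 1),
    # --- purine nucleotides ---
    ("amp", "AMP", "C10H14N5O7P", "purine", "Nucleotides", 1),
    ("adp", "ADP", "C10H15N5O10P2", "purine", "Nucleotides", 1),
    ("atp", "ATP", "C10H16N5O13P3", "purine;oxidative_phosphorylation", "Nucleotides", 1),
    ("gmp", "GMP", "C10H14N5O8P", "purine", "Nucleotides", 1),
    ("gdp", "GDP", "C10H15N5O11P2", "purine", "Nucleotides", 1),
    ("gtp", "GTP", "C10H16N5O14P3", "purine", "Nucleotides", 1),
    ("imp", "IMP", "C10H13N4O8P", "purine", "Nucleotides", 1),
    ("damp", "dAMP", "C10H14N5O6P", "purine", "Nucleotides", 1),
    ("dadp", "dADP", "C10H15N5O9P2", "purine", "Nucleotides", 1),
    ("datp", "dATP", "C10H16N5O12P3", "purine", "Nucleotides", 1),
    ("dgmp", "dGMP", "C10H14N5O7P", "purine", "Nucleotides", 1),
    ("dgdp", "dGDP", "C10H15N5O10P2", "purine", "Nucleotides", 1),
    ("dgtp", "dGTP", "C10H16N5O13P3", "purine", "Nucleotides", 1),
    # --- pyrimidine nucleotides ---
    ("cmp", "CMP", "C9H14N3O8P", "pyrimidine", "Nucleotides", 1),
    ("cdp", "CDP", "C9H15N3O11P2", "pyrimidine", "Nucleotides", 1),
    ("ctp", "CTP", "C9H16N3O14P3", "pyrimidine;kennedy", "Nucleotides", 1),
    ("ump", "UMP", "C9H13N2O9P", "pyrimidine", "Nucleotides", 1),
    ("udp", "UDP", "C9H14N2O12P2", "pyrimidine", "Nucleotides", 1),
    ("utp", "UTP", "C9H15N2O15P3", "pyrimidine;glycogen", "Nucleotides", 1),
    ("dtmp", "dTMP", "C10H15N2O8P", "pyrimidine", "Nucleotides", 1),
    ("dtdp", "dTDP", "C10H16N2O11P2", "pyrimidine", "Nucleotides", 1),
    ("dcmp", "dCMP", "C9H14N3O7P", "pyrimidine", "Nucleotides", 1),
    # --- bases and nucleosides ---
    ("ade", "adenine", "C5H5N5", "purine", "Purines", 1),
    ("gua", "guanine", "C5H5N5O", "purine", "Purines", 1),
    ("hyp", "hypoxanthine", "C5H4N4O", "purine", "Purines", 1),
    ("xan", "xanthine", "C5H4N4O2", "purine", "Purines", 1),
    ("ura", "uric acid", "C5H4N4O3", "purine", "Purines", 1),
    ("urc", "uracil", "C4H4N2O2", "pyrimidine", "Pyrimidines", 1),
    ("cyt", "cytosine", "C4H5N3O", "pyrimidine", "Pyrimidines", 1),
    ("thy", "thymine", "C5H6N2O2", "pyrimidine", "Pyrimidines", 1),
    ("ado", "adenosine", "C10H13N5O4", "purine", "Purines", 1),
    ("guo", "guanosine", "C10H13N5O5", "purine", "Purines", 1),
    ("ino", "inosine", "C10H12N4O5", "purine", "Purines", 1),
    ("urd", "uridine", "C9H12N2O6", "pyrimidine", "Pyrimidines", 1),
    ("ctd", "cytidine", "C9H13N3O5", "pyrimidine", "Pyrimidines", 1),
    ("thd", "thymidine", "C10H14N2O5", "pyrimidine", "Pyrimidines", 1),
    # --- nucleotide sugars ---
    ("udpglc", "UDP-glucose", "C15H24N2O17P2", "galactose;glycogen;nucleotide_sugar", "Carbohydrates", 1),
    ("udpgal", "UDP-galactose", "C15H24N2O17P2", "galactose;nucleotide_sugar", "Carbohydrates", 1),
    ("udpglca", "UDP-glucuronate", "C15H22N2O18P2", "nucleotide_sugar;ascorbate_aldarate;glycosaminoglycan", "Carbohydrates", 1),
    ("udpglcnac", "UDP-N-acetylglucosamine", "C17H27N3O17P2", "hexosamine;nucleotide_sugar;glycosaminoglycan", "Carbohydrates", 1),
    ("gdpman", "GDP-mannose", "C16H25N5O16P2", "fructose_mannose;nucleotide_sugar", "Carbohydrates", 1),
    # --- Kennedy pathway / glycerophospholipid ---
    ("pcho", "phosphocholine", "C5H14NO4P", "kennedy;glycerophospholipid", "Organonitrogen compounds", 1),
    ("cdpcho", "CDP-choline", "C14H26N4O11P2", "kennedy;glycerophospholipid", "Nucleotides", 1),
    ("etn", "ethanolamine", "C2H7NO", "kennedy;glycerophospholipid", "Organonitrogen compounds", 1),
    ("petn", "ethanolamine phosphate", "C2H8NO4P", "kennedy;glycerophospholipid;sphingolipid", "Organonitrogen compounds", 1),
    ("cdpetn", "CDP-ethanolamine", "C11H20N4O11P2", "kennedy;glycerophospholipid", "Nucleotides", 1),
    ("gpc", "glycerophosphocholine", "C8H20NO6P", "glycerophospholipid", "Glycerophospholipids", 1),
    ("gpe", "glycerophosphoethanolamine", "C5H14NO6P", "glycerophospholipid", "Glycerophospholipids", 1),
    ("glyc", "glycerol", "C3H8O3", "glycerophospholipid;galactose", "Organooxygen compounds", 1),
    ("g3p", "glycerol 3-phosphate", "C3H9O6P", "glycerophospholipid;glycolysis", "Organooxygen compounds", 1),
    ("lpa160", "LPA(16:0)", "C19H39O7P", "glycerophospholipid", "Glycerophospholipids", 1),
    ("lpe160", "LPE(16:0)", "C21H44NO7P", "glycerophospholipid", "Glycerophospholipids", 1),
    ("lpc160", "LPC(16:0)", "C24H50NO7P", "glycerophospholipid", "Glycerophospholipids", 1),
    ("pe341", "PE(34:1)", "C39H76NO8P", "glycerophospholipid", "Glycerophospholipids", 1),
    ("pa341", "PA(34:1)", "C37H71O8P", "glycerophospholipid", "Glycerophospholipids", 1),
    # --- sphingolipid ---
    ("sph", "sphingosine", "C18H37NO2", "sphingolipid", "Phosphosphingolipids", 1),
    ("s1p", "sphingosine 1-phosphate", "C18H38NO5P", "sphingolipid", "Phosphosphingolipids", 1),
    ("spa", "sphinganine", "C18H39NO2", "sphingolipid", "Phosphosphingolipids", 1),
    # --- cysteine / methionine ---
    ("met", "methionine", "C5H11NO2S", "cys_met", "Amino acids and peptides", 1),
    ("hcy", "homocysteine", "C4H9NO2S", "cys_met", "Amino acids and peptides", 1),
    ("cysta", "cystathionine", "C7H14N2O4S", "cys_met", "Amino acids and peptides", 1),
    ("sah", "S-adenosylhomocysteine", "C14H20N6O5S", "cys_met", "Nucleotides", 1),
    ("sam", "S-adenosylmethionine", "C15H22N6O5S", "cys_met", "Nucleotides", 1),
    ("cya", "cysteate", "C3H7NO5S", "cys_met;taurine", "Organic sulfuric acids", 1),
    ("pser", "O-phosphoserine", "C3H8NO6P", "cys_met;aa_biosynthesis", "Amino acids and peptides", 1),
    ("oxb", "2-oxobutanoate", "C4H6O3", "cys_met", "Organic acids", 1),
    ("spyr", "3-sulfinylpyruvate", "C3H4O5S", "cys_met", "Organic sulfuric acids", 1),
    ("mta", "5'-methylthioadenosine", "C11H15N5O3S", "cys_met", "Purines", 1),
    ("gsh", "glutathione", "C10H17N3O6S", "glutathione;cys_met", "Amino acids and peptides", 1),
    ("gssg", "glutathione disulfide", "C20H32N6O12S2", "glutathione", "Amino acids and peptides", 1),
    ("tau", "taurine", "C2H7NO3S", "taurine", "Organic sulfuric acids", 1),
    ("htau", "hypotaurine", "C2H7NO2S", "taurine", "Organic sulfuric acids", 1),
    ("csa", "cysteine sulfinate", "C3H7NO4S", "cys_met;taurine", "Organic sulfuric acids", 1),
    # --- inositol ---
    ("ins", "myo-inositol", "C6H12O6", "inositol_p;galactose", "Organooxygen compounds", 1),
    ("ins1p", "myo-inositol phosphate", "C6H13O9P", "inositol_p", "Organooxygen compounds", 1),
    ("ins2p", "myo-inositol bisphosphate", "C6H14O12P2", "inositol_p", "Organooxygen compounds", 1),
    # --- galactose metabolism ---
    ("gal", "galactose", "C6H12O6", "galactose", "Carbohydrates", 1),
    ("gal1p", "galactose 1-phosphate", "C6H13O9P", "galactose", "Carbohydrates", 1),
    ("galtol", "galactitol", "C6H14O6", "galactose", "Carbohydrates", 1),
    ("lactose", "lactose", "C12H22O11", "galactose", "Carbohydrates", 1),
    ("sucr", "sucrose", "C12H22O11", "starch_sucrose", "Carbohydrates", 1),
    ("sorb", "sorbitol", "C6H14O6", "fructose_mannose;galactose", "Carbohydrates", 1),
    ("raff", "raffinose", "C18H32O16", "galactose", "Carbohydrates", 1),
    # --- TCA cycle ---
    ("cit", "citrate", "C6H8O7", "tca", "Organic acids", 1),
    ("icit", "isocitrate", "C6H8O7", "tca", "Organic acids", 1),
    ("acon", "cis-aconitate", "C6H6O6", "tca", "Organic acids", 1),
    ("akg", "2-oxoglutarate", "C5H6O5", "tca", "Organic acids", 1),
    ("suc", "succinate", "C4H6O4", "tca", "Organic acids", 1),
    ("fum", "fumarate", "C4H4O4", "tca;arginine", "Organic acids", 1),
    ("mal", "malate", "C4H6O5", "tca", "Organic acids", 1),
    ("oaa", "oxaloacetate", "C4H4O5", "tca", "Organic acids", 1),
    # --- arginine / polyamines ---
    ("orn", "ornithine", "C5H12N2O2", "arginine", "Amino acids and peptides", 1),
    ("citl", "citrulline", "C6H13N3O3", "arginine", "Amino acids and peptides", 1),
    ("argsuc", "argininosuccinate", "C10H18N4O6", "arginine", "Amino acids and peptides", 1),
    ("urea", "urea", "CH4N2O", "arginine", "Organonitrogen compounds", 1),
    ("crea", "creatine", "C4H9N3O2", "arginine", "Amino acids and peptides", 1),
    ("crn", "creatinine", "C4H7N3O", "arginine", "Organonitrogen compounds", 1),
    ("pcrea", "phosphocreatine", "C4H10N3O5P", "arginine", "Amino acids and peptides", 1),
    ("put", "putrescine", "C4H12N2", "arginine", "Organonitrogen compounds", 1),
    ("spd", "spermidine", "C7H19N3", "arginine", "Organonitrogen compounds", 1),
    ("gaa", "guanidinoacetate", "C3H7N3O2", "arginine", "Amino acids and peptides", 1),
    # --- ascorbate / aldarate ---
    ("asc", "ascorbate", "C6H8O6", "ascorbate_aldarate", "Vitamins and cofactors", 1),
    ("dha", "dehydroascorbate", "C6H6O6", "ascorbate_aldarate", "Vitamins and cofactors", 1),
    ("glcr", "glucarate", "C6H10O8", "ascorbate_aldarate", "Organic acids", 1),
    ("galr", "galactarate", "C6H10O8", "ascorbate_aldarate", "Organic acids", 1),
    ("glcn", "gluconate", "C6H12O7", "ppp", "Organic acids", 1),
    ("glca", "glucuronate", "C6H10O7", "ascorbate_aldarate;inositol_p", "Carbohydrates", 1),
    ("gala", "galacturonate", "C6H10O7", "ascorbate_aldarate", "Carbohydrates", 1),
    # --- amino acids ---
    ("gly", "glycine", "C2H5NO2", "glutathione;aa_biosynthesis", "Amino acids and peptides", 1),
    ("ala", "alanine", "C3H7NO2", "aa_biosynthesis", "Amino acids and peptides", 1),
    ("ser", "serine", "C3H7NO3", "cys_met;aa_biosynthesis", "Amino acids and peptides", 1),
    ("pro", "proline", "C5H9NO2", "arginine;aa_biosynthesis", "Amino acids and peptides", 1),
    ("val", "valine", "C5H11NO2", "aa_biosynthesis", "Amino acids and peptides", 1),
    ("thr", "threonine", "C4H9NO3", "aa_biosynthesis", "Amino acids and peptides", 1),
    ("cys", "cysteine", "C3H7NO2S", "cys_met;glutathione;taurine", "Amino acids and peptides", 1),
    ("leu", "leucine", "C6H13NO2", "aa_biosynthesis", "Amino acids and peptides", 1),
    ("ile", "isoleucine", "C6H13NO2", "aa_biosynthesis", "Amino acids and peptides", 1),
    ("asn", "asparagine", "C4H8N2O3", "aa_biosynthesis", "Amino acids and peptides", 1),
    ("asp", "aspartate", "C4H7NO4", "cys_met;arginine;aa_biosynthesis", "Amino acids and peptides", 1),
    ("gln", "glutamine", "C5H10N2O3", "aa_biosynthesis", "Amino acids and peptides", 1),
    ("glu", "glutamate", "C5H9NO4", "glutathione;arginine;aa_biosynthesis", "Amino acids and peptides", 1),
    ("lys", "lysine", "C6H14N2O2", "aa_biosynthesis", "Amino acids and peptides", 1),
    ("his", "histidine", "C6H9N3O2", "aa_biosynthesis", "Amino acids and peptides", 1),
    ("phe", "phenylalanine", "C9H11NO2", "aa_biosynthesis", "Amino acids and peptides", 1),
    ("arg", "arginine", "C6H14N4O2", "arginine", "Amino acids and peptides", 1),
    ("tyr", "tyrosine", "C9H11NO3", "aa_biosynthesis", "Amino acids and peptides", 1),
    ("trp", "tryptophan", "C11H12N2O2", "aa_biosynthesis", "Amino acids and peptides", 1),
    ("gaba", "4-aminobutanoate", "C4H9NO2", "arginine", "Amino acids and peptides", 1),
    ("naa", "N-acetylaspartate", "C6H9NO5", "aa_biosynthesis", "Amino acids and peptides", 1),
    # --- fatty acids ---
    ("fa120", "laurate", "C12H24O2", "fatty_acid", "Fatty acids", 1),
    ("fa140", "myristate", "C14H28O2", "fatty_acid", "Fatty acids", 1),
    ("fa160", "palmitate", "C16H32O2", "fatty_acid", "Fatty acids", 1),
    ("fa161", "palmitoleate", "C16H30O2", "fatty_acid", "Fatty acids", 1),
    ("fa180", "stearate", "C18H36O2", "fatty_acid", "Fatty acids", 1),
    ("fa181", "oleate", "C18H34O2", "fatty_acid", "Fatty acids", 1),
    ("fa182", "linoleate", "C18H32O2", "fatty_acid", "Fatty acids", 1),
    ("fa204", "arachidonate", "C20H32O2", "fatty_acid", "Fatty acids", 1),
    ("fa226", "docosahexaenoate", "C22H32O2", "fatty_acid", "Fatty acids", 1),
    # --- cofactors / vitamins ---
    ("nad", "NAD+", "C21H27N7O14P2", "nicotinate;oxidative_phosphorylation", "Vitamins and cofactors", 1),
    ("nadh", "NADH", "C21H29N7O14P2", "nicotinate;oxidative_phosphorylation", "Vitamins and cofactors", 1),
    ("nadp", "NADP+", "C21H28N7O17P3", "nicotinate;ppp", "Vitamins and cofactors", 1),
    ("fad", "FAD", "C27H33N9O15P2", "riboflavin", "Vitamins and cofactors", 1),
    ("fmn", "FMN", "C17H21N4O9P", "riboflavin", "Vitamins and cofactors", 1),
    ("ribofl", "riboflavin", "C17H20N4O6", "riboflavin", "Vitamins and cofactors", 1),
    ("nam", "nicotinamide", "C6H6N2O", "nicotinate", "Vitamins and cofactors", 1),
    ("nac", "nicotinate", "C6H5NO2", "nicotinate", "Vitamins and cofactors", 1),
    ("pant", "pantothenate", "C9H17NO5", "pantothenate", "Vitamins and cofactors", 1),
    ("plp", "pyridoxal 5'-phosphate", "C8H10NO6P", "vitamin_b6", "Vitamins and cofactors", 1),
    ("pdx", "pyridoxine", "C8H11NO3", "vitamin_b6", "Vitamins and cofactors", 1),
    ("btn", "biotin", "C10H16N2O3S", "biotin", "Vitamins and cofactors", 1),
    ("fol", "folate", "C19H19N7O6", "folate", "Vitamins and cofactors", 1),
    ("coa", "coenzyme A", "C21H36N7O16P3S", "pantothenate", "Vitamins and cofactors", 1),
    # --- amino sugars ---
    ("gln6p", "glucosamine 6-phosphate", "C6H14NO8P", "hexosamine", "Carbohydrates", 1),
    ("glcn0", "glucosamine", "C6H13NO5", "hexosamine", "Carbohydrates", 1),
    ("glcnac", "N-acetylglucosamine", "C8H15NO6", "hexosamine;glycosaminoglycan", "Carbohydrates", 1),
    ("neuac", "N-acetylneuraminate", "C11H19NO9", "hexosamine", "Carbohydrates", 1),
    # --- carnitines / misc ---
    ("car", "carnitine", "C7H15NO3", "fatty_acid", "Organonitrogen compounds", 1),
    ("acar", "acetylcarnitine", "C9H17NO4", "fatty_acid", "Organonitrogen compounds", 1),
    ("bet", "betaine", "C5H11NO2", "glycerophospholipid", "Organonitrogen compounds", 1),
    # --- exogenous decoys (drugs, pesticides, matrix) ---
    ("x9aa", "9-aminoacridine", "C13H10N2", "", "Matrix compound", 0),
    ("xcaf", "caffeine", "C8H10N4O2", "", "Drug", 0),
    ("xapap", "acetaminophen", "C8H9NO2", "", "Drug", 0),
    ("xibu", "ibuprofen", "C13H18O2", "", "Drug", 0),
    ("xatz", "atrazine", "C8H14ClN5", "", "Pesticide", 0),
    ("xgly", "glyphosate", "C3H8NO5P", "", "Pesticide", 0),
    ("xcbz", "carbamazepine", "C15H12N2O", "", "Drug", 0),
    ("xwar", "warfarin", "C19H16O4", "", "Drug", 0),
    ("xdeet", "DEET", "C12H17NO", "", "Pesticide", 0),
    ("xnic", "nicotine", "C10H14N2", "", "Alkaloid", 0),
    ("xmet", "metformin", "C4H11N5", "", "Drug", 0),
]


def main() -> None:
    data_dir = ROOT / "src" / "bonemsi" / "data"
    data_dir.mkdir(parents=True, exist_ok=True)

    ids = [m[0] for m in METABOLITES]
    assert len(ids) == len(set(ids)), "duplicate ids"

    lines = ["id\tname\tformula\tmass\tpathways\tclass\tendogenous"]
    for mid, name, formula, pathways, chem_class, endo in METABOLITES:
        mass = neutral_mass(formula)
        lines.append(
            f"{mid}\t{name}\t{formula}\t{mass:.6f}\t{pathways}\t{chem_class}\t{endo}"
        )
    (data_dir / "metabolites.tsv").write_text("\n".join(lines) + "\n")

    glines = ["residue\tformula"]
    for residue, formula in GLYCAN_RESIDUES.items():
        glines.append(f"{residue}\t{formula}")
    (data_dir / "glycan_residues.tsv").write_text("\n".join(glines) + "\n")

    print(f"wrote {len(METABOLITES)} metabolites, {len(GLYCAN_RESIDUES)} residues")


if __name__ == "__main__":
    main()
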