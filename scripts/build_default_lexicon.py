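"""Author the packaged default head-CT lexicon and emit the checked-in TSV.

The dictionary structure (5 categories, 64 entities, 469 terms, 13 decoder
groups, negation / uncertainty / end-line subroles, chronic / recent-past /
extracranial markers) follows the published description of such head-CT
entity dictionaries; the concrete term inventory is authored here and is
fully replaceable through the lexicon file interface.

Run from the repository root:

    python scripts/build_default_lexicon.py
"""

from __future__ import annotations

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from headct_nlp.lexicon import (  # noqa: E402
    EntityDef,
    Lexicon,
    TermEntry,
    validate_lexicon,
    write_lexicon,
)

# (entity, category, subrole, decoder_group, marker, [terms])
# marker: "" none, "C" chronic, "R" recent-past, "X" extracranial — applied
# to every term of the entity.
SPEC: list[tuple[str, str, str, str, str, list[str]]] = [
    # ------------------------------------------------------------------ INJURY
    ("hemorrhage", "INJURY", "", "hemorrhage", "", [
        "hemorrhage", "hemorrhages", "haemorrhage", "haemorrhages",
        "hemorrhagic", "bleed", "bleeding", "rebleeding",
        "intracranial hemorrhage", "intracerebral hemorrhage",
        "intraventricular hemorrhage", "ich", "ivh",
    ]),
    ("hematoma", "INJURY", "", "hemorrhage", "", [
        "hematoma", "hematomas", "haematoma",
        "subdural hematoma", "epidural hematoma", "intraparenchymal hematoma",
    ]),
    ("subarachnoid_hemorrhage", "INJURY", "", "hemorrhage", "", [
        "subarachnoid hemorrhage", "subarachnoid haemorrhage",
        "subarachnoid blood", "sah",
    ]),
    ("microhemorrhage", "INJURY", "", "hemorrhage", "", [
        "microhemorrhage", "microhemorrhages", "microbleed", "microbleeds",
    ]),
    ("contusion", "INJURY", "", "hemorrhage", "", [
        "contusion", "contusions", "hemorrhagic contusion",
        "hemorrhagic contusions", "contusional",
    ]),
    ("stroke", "INJURY", "", "stroke", "", [
        "stroke", "strokes", "cva",
    ]),
    ("infarct", "INJURY", "", "stroke", "", [
        "infarct", "infarcts", "infarction", "infarctions",
        "lacunar infarct", "lacunar infarcts", "lacune", "lacunes",
        "watershed infarct", "territorial infarct",
    ]),
    ("ischemia", "INJURY", "", "stroke", "", [
        "ischemia", "ischaemia", "ischemic change", "ischemic changes",
        "hypoperfusion",
    ]),
    ("hydrocephalus", "INJURY", "", "hydrocephalus", "", [
        "hydrocephalus", "ventriculomegaly", "ventricular dilatation",
        "ventricular dilation", "obstructive hydrocephalus",
        "communicating hydrocephalus",
    ]),
    ("craniotomy", "INJURY", "", "surgical_intervention", "", [
        "craniotomy", "craniectomy", "hemicraniectomy",
        "burr hole", "burr holes", "bone flap", "craniotomy defect",
    ]),
    ("catheter", "INJURY", "", "surgical_intervention", "", [
        "catheter", "ventricular catheter", "ventriculostomy", "evd",
        "shunt", "ventriculoperitoneal shunt", "vp shunt", "drain",
        "drainage catheter",
    ]),
    ("postsurgical_change", "INJURY", "", "surgical_intervention", "", [
        "postsurgical change", "postsurgical changes",
        "postoperative change", "postoperative changes", "surgical hardware",
    ]),
    ("herniation", "INJURY", "", "herniation", "", [
        "herniation", "herniations", "uncal herniation",
        "tonsillar herniation", "subfalcine herniation",
        "transtentorial herniation", "downward herniation",
    ]),
    ("mass_effect", "INJURY", "", "mass_effect", "", [
        "mass effect", "local mass effect", "effacement",
        "sulcal effacement", "effacement of sulci", "compression",
    ]),
    ("midline_shift", "INJURY", "", "midline_shift", "", [
        "midline shift", "shift of midline", "midline deviation",
        "shift of the midline structures",
    ]),
    ("edema", "INJURY", "", "edema", "", [
        "edema", "oedema", "swelling", "cerebral edema",
        "vasogenic edema", "cytotoxic edema", "perilesional edema",
    ]),
    ("fluid_collection", "INJURY", "", "fluid", "", [
        "fluid collection", "fluid collections", "fluid",
        "hygroma", "hygromas", "extra-axial collection",
        "extra-axial collections",
    ]),
    ("effusion", "INJURY", "", "fluid", "", [
        "effusion", "effusions",
    ]),
    ("lesion", "INJURY", "", "lesion", "", [
        "lesion", "lesions",
    ]),
    ("mass", "INJURY", "", "lesion", "", [
        "mass", "masses", "tumor", "neoplasm", "metastasis", "metastases",
    ]),
    ("cyst", "INJURY", "", "lesion", "", [
        "cyst", "cysts", "cystic",
    ]),
    ("pneumocephalus", "INJURY", "", "pneumocephalus", "", [
        "pneumocephalus", "pneumocephaly", "intracranial air",
        "intracranial gas",
    ]),
    ("vascular_malformation", "INJURY", "", "vascular_malformation", "", [
        "vascular malformation", "arteriovenous malformation", "avm",
        "cavernoma", "cavernous malformation", "dural arteriovenous fistula",
    ]),
    ("aneurysm", "INJURY", "", "vascular_malformation", "", [
        "aneurysm", "aneurysms", "aneurysmal",
    ]),
    ("high_density", "INJURY", "", "density", "", [
        "high density", "hyperdensity", "hyperdense", "hyperdensities",
        "high attenuation", "hyperattenuation",
    ]),
    ("low_density", "INJURY", "", "density", "", [
        "low density", "hypodensity", "hypodense", "hypodensities",
        "low attenuation", "hypoattenuation",
    ]),
    ("mixed_density", "INJURY", "", "density", "", [
        "mixed density", "mixed densities", "mixed attenuation",
        "heterogeneous density", "heterogeneous attenuation",
    ]),
    ("density_unspecified", "INJURY", "", "density", "", [
        "density", "densities", "attenuation change",
        "attenuation abnormality",
    ]),
    # Chronic-disease descriptions: ignored by the decoder (no decoder group
    # would already exclude them, but the marker also suppresses decoder-group
    # injuries mentioned in the same breath, e.g. "chronic ... infarct").
    ("chronic_disease", "INJURY", "", "", "C", [
        "small vessel ischemic disease", "small vessel disease",
        "microvascular ischemic change", "microvascular ischemic changes",
        "chronic microangiopathy", "atrophy", "atrophic change",
        "volume loss", "encephalomalacia", "gliosis", "leukoaraiosis",
        "leukomalacia", "involutional change", "involutional changes",
    ]),
    ("fracture", "INJURY", "", "", "", [
        "fracture", "fractures", "skull fracture", "nasal bone fracture",
        "facial fracture", "orbital fracture",
    ]),
    # --------------------------------------------------------------- MAGNITUDE
    ("size_measurement", "MAGNITUDE", "", "", "", [
        "<num> mm", "<num> cm",
        "<num> x <num> mm", "<num> x <num> cm",
        "<num> x <num> x <num> mm", "<num> x <num> x <num> cm",
    ]),
    ("severity", "MAGNITUDE", "", "", "", [
        "mild", "mildly", "moderate", "moderately", "severe", "severely",
        "marked", "markedly", "minimal", "minimally", "subtle", "prominent",
    ]),
    ("extent", "MAGNITUDE", "", "", "", [
        "small", "large", "tiny", "trace", "extensive", "punctate",
        "diffuse", "focal", "multifocal", "scattered", "patchy",
        "confluent", "widespread",
    ]),
    ("quantity", "MAGNITUDE", "", "", "", [
        "single", "solitary", "isolated", "multiple", "few", "several",
        "numerous", "innumerable",
    ]),
    ("volume_change", "MAGNITUDE", "", "", "", [
        "increased", "increasing", "decreased", "decreasing",
        "enlarged", "enlarging", "expanded", "expanding",
        "reduced", "worsening", "improving", "improved",
    ]),
    ("degree_qualifier", "MAGNITUDE", "", "", "", [
        "slight", "slightly", "significant", "significantly",
        "substantial", "gross", "grossly", "partial", "near complete",
    ]),
    # ---------------------------------------------------------------- LOCATION
    ("laterality", "LOCATION", "", "", "", [
        "left", "right", "left-sided", "right-sided", "left sided",
        "right sided", "bilateral", "bilaterally", "midline", "unilateral",
    ]),
    ("frontal_lobe", "LOCATION", "", "", "", [
        "frontal", "frontal lobe", "frontal lobes", "bifrontal",
    ]),
    ("parietal_lobe", "LOCATION", "", "", "", [
        "parietal", "parietal lobe", "parietal lobes", "biparietal",
    ]),
    ("temporal_lobe", "LOCATION", "", "", "", [
        "temporal", "temporal lobe", "temporal lobes", "bitemporal",
    ]),
    ("occipital_lobe", "LOCATION", "", "", "", [
        "occipital", "occipital lobe", "occipital lobes",
    ]),
    ("cerebellum", "LOCATION", "", "", "", [
        "cerebellum", "cerebellar", "cerebellar hemisphere",
        "cerebellar hemispheres", "posterior fossa", "vermis",
    ]),
    ("brainstem", "LOCATION", "", "", "", [
        "brainstem", "pons", "pontine", "midbrain", "medulla",
        "cerebral peduncle",
    ]),
    ("deep_gray", "LOCATION", "", "", "", [
        "basal ganglia", "thalamus", "thalamic", "caudate", "putamen",
        "globus pallidus", "lentiform nucleus", "internal capsule",
    ]),
    ("ventricle", "LOCATION", "", "", "", [
        "ventricle", "ventricles", "ventricular", "lateral ventricle",
        "lateral ventricles", "third ventricle", "fourth ventricle",
        "intraventricular", "temporal horn", "frontal horn",
        "occipital horn",
    ]),
    ("subdural_space", "LOCATION", "", "", "", [
        "subdural", "subdural space",
    ]),
    ("epidural_space", "LOCATION", "", "", "", [
        "epidural", "extradural",
    ]),
    ("subarachnoid_space", "LOCATION", "", "", "", [
        "subarachnoid", "subarachnoid space", "sulci", "sulcal",
        "cistern", "cisterns", "basal cisterns", "suprasellar cistern",
        "quadrigeminal cistern", "sylvian fissure",
        "interhemispheric fissure",
    ]),
    ("parenchyma", "LOCATION", "", "", "", [
        "parenchyma", "parenchymal", "intraparenchymal", "intra-axial",
        "white matter", "gray matter", "grey matter", "deep white matter",
        "periventricular", "subcortical", "cortical", "cortex",
        "centrum semiovale", "corona radiata",
    ]),
    ("extra_axial_space", "LOCATION", "", "", "", [
        "extra-axial", "extraaxial", "extra-axial space",
    ]),
    ("dural_structure", "LOCATION", "", "", "", [
        "falx", "falx cerebri", "falcine", "tentorium",
        "tentorium cerebelli", "tentorial", "dura", "dural",
    ]),
    ("region", "LOCATION", "", "", "", [
        "convexity", "convexities", "vertex", "skull base",
        "hemisphere", "hemispheres", "hemispheric", "lobe", "lobes",
        "region", "regions", "supratentorial", "infratentorial",
        "parasagittal", "parafalcine",
    ]),
    ("scalp", "LOCATION", "", "", "X", [
        "scalp", "subgaleal", "scalp soft tissues",
    ]),
    ("skull", "LOCATION", "", "", "X", [
        "skull", "calvarium", "calvarial", "cranium", "bone", "bones",
        "osseous structures", "petrous bone", "sphenoid bone",
    ]),
    ("extracranial_soft_tissue", "LOCATION", "", "", "X", [
        "soft tissue", "soft tissues", "face", "facial", "orbit", "orbits",
        "orbital", "periorbital", "globe", "globes", "sinus", "sinuses",
        "paranasal sinuses", "maxillary sinus", "ethmoid air cells",
        "mastoid", "mastoid air cells", "nasal", "nasal cavity",
    ]),
    # -------------------------------------------------------------------- TIME
    ("acuity", "TIME", "", "", "", [
        "acute", "acutely", "hyperacute", "subacute", "new", "newly",
        "recent", "recently", "early", "acute phase",
    ]),
    ("chronicity", "TIME", "", "", "C", [
        "chronic", "chronically", "old", "longstanding", "long-standing",
        "remote", "age-indeterminate", "age indeterminate", "prior",
        "previous", "preexisting", "chronic appearing",
    ]),
    ("interval_change", "TIME", "", "", "R", [
        "evolving", "stable", "redemonstrated", "redemonstration",
        "persistent", "unchanged", "essentially unchanged", "again seen",
        "again noted", "again demonstrated",
    ]),
    ("interval_reference", "TIME", "", "", "", [
        "interval", "since prior", "since the prior", "compared to prior",
        "in the interval", "interval development",
    ]),
    ("time_point", "TIME", "", "", "", [
        "at this time", "currently", "now", "today", "at present",
    ]),
    ("duration", "TIME", "", "", "", [
        "transient", "ongoing", "progressive", "progressively",
    ]),
    # ------------------------------------------------------------------- OTHER
    ("negation", "OTHER", "NEGATION", "", "", [
        "no", "not", "without", "no evidence of", "no evidence for",
        "negative for", "negative", "none", "absent", "absence of",
        "free of", "ruled out", "rather than", "resolved", "resolution of",
        "excluded", "no definite", "no new",
    ]),
    ("uncertainty", "OTHER", "UNCERTAINTY", "", "", [
        "possible", "possibly", "possibility of", "probable", "probably",
        "likely", "likely represents", "may represent", "might represent",
        "may reflect", "may be", "could represent", "cannot exclude",
        "cannot be excluded", "suspicious for", "concerning for",
        "worrisome for", "questionable", "question of", "suggestive of",
        "suggesting", "equivocal", "borderline", "versus", "vs",
    ]),
    ("end_line", "OTHER", "END_LINE", "", "", [
        ".", ";",
    ]),
]


def build() -> Lexicon:
    entities = []
    terms = []
    for name, category, subrole, group, marker, surfaces in SPEC:
        entities.append(
            EntityDef(
                name=name,
                category=category,
                subrole=subrole or None,
                decoder_group=group or None,
            )
        )
        for s in surfaces:
            terms.append(
                TermEntry(
                    surface=s,
                    entity=name,
                    chronic_marker=marker == "C",
                    recent_past_marker=marker == "R",
                    extracranial_marker=marker == "X",
                )
            )
    return Lexicon(entities=tuple(entities), terms=tuple(terms), version="default-1.0")


def main() -> None:
    lex = build()
    problems = validate_lexicon(lex)
    counts = lex.category_counts()
    per_cat_terms = {
        c: len(lex.terms_in_category(c)) for c in counts
    }
    print(f"entities: {lex.n_entities}  terms: {lex.n_terms}")
    print(f"entities by category: {counts}")
    print(f"terms by category:    {per_cat_terms}")
    if problems:
        for p in problems:
            print("VIOLATION:", p)
        sys.exit(1)
    assert lex.n_entities == 64, lex.n_entities
    assert lex.n_terms == 469, lex.n_terms
    out = Path(__file__).resolve().parents[1] / "src/headct_nlp/data/default_lexicon.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    write_lexicon(lex, out, format="tabular")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
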