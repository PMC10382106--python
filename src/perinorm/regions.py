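"""Region vocabulary for the neonatal volumetric pipeline.

Thirteen regions receive normative curves and deviation Z-scores.  Total
tissue volume is never measured directly: it is the sum of cortical gray
matter, white matter, cerebellum, brainstem, total deep gray matter (the six
deep nuclei) and the hippocampus+amygdala compartment.  The hippocampus+
amygdala volume is therefore carried through the tables as a component but
has no normative curve of its own; extracerebral CSF and the ventricles are
modelled but do not enter the total-tissue sum.
"""

TOTAL_TISSUE = "total_tissue"

DEEP_NUCLEI = (
    "caudate_l",
    "caudate_r",
    "lentiform_l",
    "lentiform_r",
    "thalamus_l",
    "thalamus_r",
)

#: Regions with their own normative curve / Z-score (13).
MODELLED_REGIONS = (
    TOTAL_TISSUE,
    "cortical_gm",
    "white_matter",
    "cerebellum",
    "brainstem",
    "csf",
    "ventricles",
) + DEEP_NUCLEI

#: Generated but not modelled; exists only so the total-tissue sum is honest.
COMPONENT_ONLY_REGIONS = ("hippocampus_amygdala",)

#: Summands of total tissue volume.
TOTAL_TISSUE_COMPONENTS = (
    "cortical_gm",
    "white_matter",
    "cerebellum",
    "brainstem",
    "hippocampus_amygdala",
) + DEEP_NUCLEI

#: Every region the simulator draws directly (everything except total tissue).
PRIMITIVE_REGIONS = tuple(
    r for r in MODELLED_REGIONS if r != TOTAL_TISSUE
) + COMPONENT_ONLY_REGIONS

ALL_REGIONS = MODELLED_REGIONS + COMPONENT_ONLY_REGIONS

CHD_CATEGORIES = ("streaming", "left", "right")
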