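"""Named constants for the AAV platform comparison.

Values in the ``REPORTED_*`` group are the study's published summary numbers
(mean harvest titers, per-unit yields, the end-to-end downstream recovery).
Vendor-nominal surface areas for the flask comparators are manufacturer data,
not study measurements, and are flagged as such.
"""

# --- per-unit crude yields (vector genomes per vessel/system per batch) ---
QUANTUM_YIELD_VG_PER_UNIT = 6.81e13
HYPERSTACK36_YIELD_VG_PER_UNIT = 1.26e14
CS10_YIELD_VG_PER_UNIT = 2.45e13

# mean crude totals from the three Quantum engineering runs
QUANTUM_YIELD_VP_PER_UNIT = 4.92e14
QUANTUM_MEAN_VG_PER_ML = 5.81e10
QUANTUM_MEAN_VP_PER_ML = 4.20e11
QUANTUM_HARVEST_VOLUME_ML = 1200.0  # "approximately 1.2 L"

# --- surface areas (cm^2) ---
QUANTUM_SURFACE_AREA_CM2 = 21_000.0  # 2.1 m^2 of hollow-fiber surface
# Vendor-nominal areas for the comparator flasks (manufacturer data):
CS10_SURFACE_AREA_CM2 = 6_360.0
HYPERSTACK36_SURFACE_AREA_CM2 = 18_000.0

# --- downstream process ---
DSP_RECOVERY = 0.30  # compounded lysate -> drug product recovery
TFF_VRF = 5.0        # volumetric reduction factor used for UF/DF

# --- dosing ---
DOSE_VG_RETINAL = 1.5e11  # vg per eye, low-dose retinal indication

# --- facility/staffing defaults ---
FACILITY_AREA_M2 = 60.0
OPERATOR_SPACE_M2 = 2.0
MAX_MSCS = 3
OPERATORS_PER_MSC = 2
FLASK_UNITS_PER_MSC = 6
QUANTUM_SYSTEMS_PER_OPERATOR_PAIR = 10

# --- in situ lysis DoE factor ranges (natural units) ---
LYSIS_CONTACT_TIME_MIN = (30.0, 240.0)
LYSIS_CELL_DENSITY_PER_ML = (1.0e6, 1.0e7)
LYSIS_TRITON_PCT = (0.2, 1.0)

# --- growth / metabolite defaults ---
# Specific rates are literature-typical HEK293 values (FIXTURE, not study
# data); sign convention: positive = produced, negative = consumed.
DEFAULT_Q_LAC_PMOL_PER_CELL_DAY = 4.0
DEFAULT_SPECIFIC_RATES_PMOL = {
    "glucose": -3.0,
    "lactate": 4.0,
    "glutamine": -0.35,
    "ammonium": 0.3,
}
DEFAULT_FEED_CONCENTRATIONS_MM = {
    "glucose": 25.0,
    "lactate": 0.0,
    "glutamine": 2.0,
    "ammonium": 0.0,
}
DEFAULT_SYSTEM_VOLUME_ML = 1500.0
GROWTH_PLATEAU_CELLS = 5.0e9
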