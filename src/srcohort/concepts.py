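"""Fixed concept catalog used across templates, converters and the generator.

Coding-scheme designators: ``SCT`` (SNOMED CT), ``LN`` (LOINC), ``DCM`` (DICOM
controlled terminology), ``UCUM`` (units), ``MDC`` (ISO/IEEE 11073 waveform
leads) and ``99SRC`` (this package's private scheme for structural concepts
without a well-known public code).

SNOMED codes in the 9000000xx range are locally assigned stand-ins, chosen
once and kept stable: concept identity inside this package is (value, scheme)
equality, so stability — not registry accuracy — is the operative requirement.
Do not treat those codes as resolvable SNOMED identifiers.
"""

from .coding import code

# --- document & section titles ---------------------------------------------
ECG_REPORT = code("11524-6", "LN", "ECG Report")
CARDIOVASCULAR_PATIENT_HISTORY = code("CPH-3802", "99SRC", "Cardiovascular Patient History")
IMAGING_MEASUREMENT_REPORT = code("126000", "DCM", "Imaging Measurement Report")
TITLE_QA_INFORMATION = code("TITLE-QA", "99SRC", "Quality Assurance Information")
TITLE_PROSTHESIS_INFORMATION = code("TITLE-PROSTH", "99SRC", "Prosthesis Information")

SOCIAL_HISTORY = code("29762-2", "LN", "Social History")
SURGICAL_HISTORY = code("10167-5", "LN", "Surgical History")
MEDICAL_DEVICE_USE = code("DEVICE-USE", "99SRC", "Medical Device Use")
PROCEDURE_CONTEXT = code("PROC-CTX", "99SRC", "Procedure Context")
MEASUREMENT_GROUP = code("125007", "DCM", "Measurement Group")
WAVEFORM_INFORMATION = code("WAVEFORM-INFO", "99SRC", "Waveform Information")
ECG_GLOBAL_MEASUREMENTS = code("ECG-MEASURES", "99SRC", "ECG Global Measurements")

# --- patient history / outcome concepts ------------------------------------
TOBACCO_SMOKER = code("77176002", "SCT", "Tobacco Smoker")
PRIOR_CARDIAC_SURGERY = code("900000010", "SCT", "History of Prior Cardiac Surgery")
DIABETES_MELLITUS = code("73211009", "SCT", "Diabetes Mellitus")
DEVICE_ITEM = code("DEVICE", "99SRC", "Device")
DEVICE_DATE = code("DEVICE-DATE", "99SRC", "Device Use Date")
COMMENT = code("121106", "DCM", "Comment")
ACQUISITION_YEAR = code("ACQ-YEAR", "99SRC", "Acquisition Year")

PACEMAKER_IMPLANTATION = code("PACEMAKER", "99SRC", "Pacemaker Implantation")
PROSTHESIS_MODEL = code("PROSTH-MODEL", "99SRC", "Prosthesis Model")
PROSTHESIS_SIZE = code("PROSTH-SIZE", "99SRC", "Prosthesis Size")
RECORD_SOURCE = code("RECORD-SOURCE", "99SRC", "Record Source")
SOURCE_QUALITY_ASSURANCE = code("SRC-QA", "99SRC", "Quality Assurance")
SOURCE_BILLING = code("SRC-BILLING", "99SRC", "Billing")
PROCEDURE_DATE = code("PROC-DATE", "99SRC", "Procedure Date")
TAVI_PROCEDURE = code("900000012", "SCT", "Transcatheter Aortic Valve Implantation")
CARDIAC_PACEMAKER = code("900000014", "SCT", "Cardiac Pacemaker")

YES = code("373066001", "SCT", "Yes")
NO = code("373067005", "SCT", "No")
UNKNOWN = code("261665006", "SCT", "Unknown")

# --- ECG measurements & findings --------------------------------------------
VENTRICULAR_RATE = code("8867-4", "LN", "Ventricular Heart Rate")
QT_INTERVAL = code("8634-8", "LN", "QT Interval")
PR_INTERVAL = code("8625-6", "LN", "PR Interval")
QRS_DURATION = code("8633-0", "LN", "QRS Duration")
RHYTHM_FINDING = code("RHYTHM-FINDING", "99SRC", "Rhythm Finding")
LEFT_BUNDLE_BRANCH_BLOCK = code("164909002", "SCT", "Left Bundle Branch Block")
SINUS_RHYTHM = code("426783006", "SCT", "Sinus Rhythm")
ATRIAL_FIBRILLATION = code("164889003", "SCT", "Atrial Fibrillation")
LEAD_SYSTEM = code("LEAD-SYSTEM", "99SRC", "Lead System")
STANDARD_12_LEAD = code("LEAD-12", "99SRC", "Standard 12-Lead")
SAMPLING_FREQUENCY = code("SAMPLING-FREQ", "99SRC", "Sampling Frequency")

# --- anatomy / findings used by annotations ---------------------------------
LEFT_VENTRICLE = code("87878005", "SCT", "left ventricle")
RIGHT_VENTRICLE = code("53085002", "SCT", "right ventricle")
RIGHT_CORONARY_CUSP = code("900000001", "SCT", "right coronary cusp")
LEFT_CORONARY_CUSP = code("900000002", "SCT", "left coronary cusp")
NON_CORONARY_CUSP = code("900000003", "SCT", "non-coronary cusp")
MEMBRANOUS_SEPTUM = code("900000004", "SCT", "membranous septum")
CALCIFICATION = code("900000005", "SCT", "calcification")
AORTIC_ROOT = code("900000006", "SCT", "aortic root")
ANATOMICAL_STRUCTURE = code("123037004", "SCT", "Anatomical Structure")

# --- units (UCUM) ------------------------------------------------------------
BEATS_PER_MINUTE = code("/min", "UCUM", "beats/min")
MILLISECOND = code("ms", "UCUM", "ms")
MILLIMETRE = code("mm", "UCUM", "mm")
HERTZ = code("Hz", "UCUM", "Hz")
MICROVOLT = code("uV", "UCUM", "uV")
NO_UNIT = code("1", "UCUM", "no units")

# --- 12-lead ECG channel sources (MDC) ---------------------------------------
LEAD_CODES = {
    "I": code("2:1", "MDC", "Lead I"),
    "II": code("2:2", "MDC", "Lead II"),
    "III": code("2:61", "MDC", "Lead III"),
    "aVR": code("2:62", "MDC", "Lead aVR"),
    "aVL": code("2:63", "MDC", "Lead aVL"),
    "aVF": code("2:64", "MDC", "Lead aVF"),
    "V1": code("2:3", "MDC", "Lead V1"),
    "V2": code("2:4", "MDC", "Lead V2"),
    "V3": code("2:5", "MDC", "Lead V3"),
    "V4": code("2:6", "MDC", "Lead V4"),
    "V5": code("2:7", "MDC", "Lead V5"),
    "V6": code("2:8", "MDC", "Lead V6"),
}
STANDARD_LEADS = tuple(LEAD_CODES)  # canonical 12-lead order
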