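"""Element-name vocabulary for the synthetic CRF generator.

Roughly 280 data-element names keyed to the 14 consensus form domains.
Names are chosen to be realistic CRF item labels while keeping distinct
elements several edit operations apart (so that the generator's typo
noise cannot silently turn one true element into another within the
default matching thresholds).  The SAE subset of the Adverse Event
domain is listed separately because the generator can force it into
every AE form.
"""

from __future__ import annotations

#: SAE reporting items (subset of the AE domain vocabulary).
SAE_ELEMENTS: tuple[str, ...] = (
    "Seriousness",
    "Action Taken",
    "Autopsy Report",
    "Date of Death",
    "Outcome",
    "Severity",
    "Verbatim Description",
)

VOCABULARY: dict[str, tuple[str, ...]] = {
    "DM": (
        "Birth Date", "Age", "Sex", "Race", "Ethnicity",
        "Country of Residence", "Subject Identifier", "Site Identifier",
        "Informed Consent Date", "Marital Status", "Education Level",
        "Occupation", "Childbearing Potential", "Enrollment Date",
        "Screening Number", "Randomization Number", "Preferred Language",
        "Insurance Status", "Legal Guardian", "Residence Type",
    ),
    "MH": (
        "Medical History Term", "Condition Ongoing", "Diagnosis Date",
        "Surgical History", "Family History of Cancer", "Allergy History",
        "Hypertension History", "Diabetes Mellitus History",
        "Myocardial Infarction History", "Stroke History", "Asthma History",
        "Depression History", "Renal Disease History",
        "Hepatic Disease History", "Thyroid Disorder History",
        "Epilepsy History", "Prior Malignancy", "Smoking Related Illness",
        "Childhood Illnesses", "Immunization History",
    ),
    "AE": (
        "Adverse Event Term", "Start Date", "End Date", "Severity",
        "Seriousness", "Action Taken", "Outcome", "Causality Assessment",
        "Date of Death", "Autopsy Report", "Hospitalization Required",
        "Life Threatening", "Congenital Anomaly", "Disability",
        "Verbatim Description", "Relationship to Study Drug",
        "Event Ongoing", "Treatment Required", "Death Cause",
        "Dechallenge Result", "Rechallenge Result", "MedDRA Code",
    ),
    "LB": (
        "Bilirubin, total", "Hemoglobin", "Hematocrit", "Platelet Count",
        "White Blood Cell Count", "Red Blood Cell Count", "Serum Creatinine",
        "Blood Urea Nitrogen", "Alanine Aminotransferase",
        "Aspartate Aminotransferase", "Alkaline Phosphatase", "Serum Sodium",
        "Serum Potassium", "Calcium", "Serum Glucose", "Total Cholesterol",
        "Triglycerides", "HbA1c", "Prothrombin Time",
        "Activated Partial Thromboplastin Time", "Serum Albumin",
        "C Reactive Protein", "Urine Protein", "Lymphocyte Count",
    ),
    "VS": (
        "Heart Rate", "Systolic Blood Pressure", "Diastolic Blood Pressure",
        "Respiratory Rate", "Body Temperature", "Height", "Weight",
        "Body Mass Index", "Oxygen Saturation", "Body Surface Area",
        "Waist Circumference", "Hip Circumference", "Pulse Regularity",
        "Body Position", "Vital Signs Date", "Temperature Location",
        "Blood Pressure Location", "Heart Rhythm",
        "Mid Upper Arm Circumference", "Pulse Oximetry Device",
    ),
    "CM": (
        "Medication Name", "Dose", "Dose Unit", "Dosing Frequency",
        "Route of Administration", "Indication", "Medication Start Date",
        "Medication End Date", "Ongoing Medication", "ATC Code",
        "Prior Medication Flag", "Dose Form", "Treatment Cycle",
        "Drug Batch Number", "Prescribing Physician", "Generic Name",
        "Trade Name", "Dose Adjustment Reason", "Compliance Percentage",
        "Infusion Duration",
    ),
    "QS": (
        "Questionnaire Name", "Question Text", "Total Score",
        "Subscale Score", "Assessment Date", "Pain Score", "Fatigue Score",
        "Quality of Life Score", "Anxiety Score", "Depression Scale Score",
        "Mobility Rating", "Self Care Rating", "Usual Activities Rating",
        "Sleep Quality Rating", "Appetite Rating", "Global Health Rating",
        "Completion Status", "Respondent Type", "Interview Mode",
        "Missing Item Count",
    ),
    "DS": (
        "Disposition Status", "Date of Discontinuation",
        "Reason for Discontinuation", "Study Completion Flag",
        "Withdrawal of Consent Date", "Lost to Follow Up Flag",
        "Last Contact Date", "Last Dose Date", "End of Study Date",
        "Early Termination Reason", "Protocol Deviation Flag",
        "Screen Failure Reason", "Randomized Flag",
        "Treatment Discontinued Flag", "Disposition Event Term", "Epoch",
        "Transfer to Other Facility", "Continuation in Extension Study",
        "Final Visit Number", "Eligibility Confirmed",
    ),
    "EG": (
        "ECG Date", "Ventricular Rate", "PR Interval", "QRS Duration",
        "QT Interval", "Corrected QT Interval", "Rhythm Interpretation",
        "ECG Abnormal Flag", "T Wave Abnormality", "ST Segment Depression",
        "ST Segment Elevation", "Atrial Fibrillation Present",
        "Left Bundle Branch Block", "Heart Axis", "Pacemaker Rhythm",
        "ECG Technician", "Lead Placement", "Sinus Rhythm Flag",
        "Premature Beats Count", "ECG Machine Identifier",
    ),
    "ZC": (
        "Primary Diagnosis", "Date of First Diagnosis", "Disease Stage",
        "Tumor Grade", "Histology Type", "Primary Tumor Site",
        "Metastasis Present", "Number of Metastatic Sites",
        "ECOG Performance Status", "Karnofsky Performance Score",
        "Disease Duration", "Symptom Onset Date", "Baseline Severity",
        "NYHA Class", "Ejection Fraction", "Viral Load at Baseline",
        "CD4 Count at Baseline", "Seizure Frequency", "Lesion Count",
        "Disease Subtype",
    ),
    "SU": (
        "Smoking Status", "Cigarettes per Day", "Years Smoked",
        "Smoking Cessation Date", "Alcohol Use Status",
        "Alcohol Units per Week", "Alcohol Type", "Caffeine Intake",
        "Caffeinated Beverages per Day", "Recreational Drug Use",
        "Drug Type Used", "Substance Use Start Date",
        "Substance Use End Date", "Pack Years", "Tobacco Type",
        "Smokeless Tobacco Use", "Passive Smoking Exposure",
        "Intravenous Drug Use", "Former Smoker Flag", "Age Started Smoking",
    ),
    "SURGERY": (
        "Surgery Date", "Procedure Name", "ICD Procedure Code",
        "Anesthesia Type", "Operative Time", "Estimated Blood Loss",
        "Surgeon Identifier", "Surgical Site", "Wound Classification",
        "Complication Flag", "Intraoperative Findings",
        "Implant Present Flag", "Implant Type", "Resection Margin Status",
        "Drain Placed", "Hospital Stay Duration", "Postoperative Infection",
        "Reoperation Required", "Recovery Room Time",
        "Discharge Destination",
    ),
    "PE": (
        "Physical Exam Date", "General Appearance", "Head and Neck Findings",
        "Cardiovascular Findings", "Respiratory Findings",
        "Abdominal Findings", "Neurological Findings", "Skin Findings",
        "Musculoskeletal Findings", "Lymph Node Examination",
        "Eye Examination Result", "Ear Nose Throat Findings",
        "Genitourinary Findings", "Extremities Findings",
        "Overall Assessment", "Abnormality Detected Flag",
        "Examining Physician", "Breast Examination Result",
        "Rectal Examination Result", "Thyroid Palpation Result",
    ),
    "RS": (
        "Overall Response", "Best Overall Response",
        "Target Lesion Measurement", "Non Target Lesion Status",
        "New Lesion Flag", "Response Assessment Date", "Progression Date",
        "Time to Progression", "Sum of Lesion Diameters", "RECIST Version",
        "Complete Response Date", "Partial Response Flag",
        "Stable Disease Duration", "Progressive Disease Flag",
        "Method of Assessment", "Imaging Modality", "Tumor Marker Level",
        "Bone Scan Result", "Evaluability Status", "Date of Best Response",
    ),
}


def element_catalog() -> list[tuple[str, str, str]]:
    """Flat (element_id, domain_key, label) catalog in a fixed order."""
    out = []
    k = 0
    for dom in VOCABULARY:
        for label in VOCABULARY[dom]:
            k += 1
            out.append((f"E{k:04d}", dom, label))
    return out
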