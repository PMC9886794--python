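trait	category
coronary heart disease	cardiovascular
coronary artery disease	cardiovascular
myocardial infarction	cardiovascular
homocysteine levels	cardiovascular
blood pressure	cardiovascular
stroke	cardiovascular
type 2 diabetes	metabolic
fasting glucose	metabolic
body mass index	metabolic
obesity	metabolic
cholesterol	metabolic
triglycerides	metabolic
hdl cholesterol	metabolic
ldl cholesterol	metabolic
alzheimer's disease	neurodegenerative
parkinson's disease	neurodegenerative
cognitive decline	neurodegenerative
macular degeneration	neurodegenerative
rheumatoid arthritis	inflammatory
crohn's disease	inflammatory
ulcerative colitis	inflammatory
inflammatory bowel disease	inflammatory
c-reactive protein	inflammatory
prostate cancer	cancer
breast cancer	cancer
colorectal cancer	cancer
lung cancer	cancer
osteoporosis	musculoskeletal
bone mineral density	musculoskeletal
chronic kidney disease	renal
estimated glomerular filtration rate	renal
lifespan	lifespan
aging	aging
longevity	longevity
parental longevity	longevity
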