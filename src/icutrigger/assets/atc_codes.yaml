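# Mini ATC dictionary: drugs suspected of causing ADRs in adult ICU cohorts,
# the trigger-list drugs, and common ICU background medication. Keys are
# lower-case generic names.
codes:
  regular insulin: A10AB01
  morphine: N02AA01
  enoxaparin: B01AB05
  heparin: B01AB01
  fentanyl: N01AH01
  amikacin: J01GB06
  amiodarone: C01BD01
  bromopride: A03FA04
  furosemide: C03CA01
  ripe: J04AM06
  risperidone: N05AX08
  tramadol: N02AX02
  ampicillin + sulbactam: J01CR01
  amphotericin b: J02AA01
  carvedilol: C07AG02
  clopidogrel: B01AC04
  scopolamine: A04AD01
  spironolactone: C03DA01
  hydralazine: C02DB01
  hydrochlorothiazide: C03AA03
  lactulose: A06AD11
  levomepromazine: N05AA02
  metoclopramide: A03FA01
  neostigmine: N07AA01
  sulfamethoxazole + trimethoprim: J01EE01
  warfarin: B01AA03
  # trigger-list drugs
  ondansetron: A04AA01
  phytomenadione: B02BA01
  flumazenil: V03AB25
  naloxone: V03AB15
  protamine: V03AB14
  dexchlorpheniramine: R06AB02
  hydroxyzine: N05BB01
  diphenhydramine: R06AA02
  loratadine: R06AX13
  hydrocortisone: H02AB09
  methylprednisolone: H02AB04
  promethazine: R06AD02
  prednisone: H02AB07
  # background ICU drugs
  midazolam: N05CD08
  norepinephrine: C01CA03
  omeprazole: A02BC01
  ceftriaxone: J01DD04
  paracetamol: N02BE01
  dipyrone: N02BB02
  vancomycin: J01XA01
  cefepime: J01DE01
  amlodipine: C08CA01
  simvastatin: C10AA01
  levothyroxine: H03AA01
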