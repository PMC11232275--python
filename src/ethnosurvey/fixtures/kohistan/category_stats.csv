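code,description,ailments,nbt,nur,exemplar_species,exemplar_uses,exemplar_fc,exemplar_um
OTHA-A,General and unspecified,"fever; allergy; back pain; typhoid fever; spiritual uses",13,398,Ajuga integrifolia,fever,14,11
GAS-D,Digestive problems,"constipation; toothache; intestinal worms; diarrhea; jaundice; indigestion; stomach pain; mouth gums; liver disorder; appetizer; abdominal worms; hepatitis; intestinal ulcers; obesity",40,114,Mentha longifolia,diarrhea and indigestion,14,13
CAR-K,Cardiovascular diseases,"blood pressure; blood purifier",2,73,Ziziphus jujuba,blood purifier,13,10
Blood-B,"Blood, blood-forming organs, and immune mechanism","blood clots; bleeding injuries; stop bleeding",4,117,Plocama brevifolia,bleeding cuts or wounds,15,7
SKE-L,Musculoskeletal disorders,"joint swelling; strengthen bones",3,122,Datisca cannabina,joint swelling,14,8
NER-N,Neurological problems,paralysis,1,26,Indigofera tinctoria,paralysis,12,5
RES-R,Respiratory disorders,"flu; cough; corona infection; chest pain; asthma; common cold; bronchitis; throat infection; influenza",17,479,Lepidium sativum,asthma,14,9
DER-S,Skin diseases,"wound healing; eczema; skin rashes; dandruff; warts; face stains; skin infection; mole removal",19,549,Myrtus communis,eczema,18,17
URO-U,Urological disorders,"urinary disorder; bladder infection; kidney inflammation; urinary tract infection",5,119,Clematis grata,urinary disorder,12,8
CAN-C,Cancer,tumors,1,26,Pteridium esculentum,tumor,12,5
PRE-W,"Pregnancy, childbearing, family planning",labor pain,1,26,Verbascum thapsus,labor pain and respiratory disorders,12,7
OTH,Others,"anti-rodents; mosquito repellent; pest repellent; fungus killer; livestock diseases; poultry ailments; antimicrobial",19,431,Ambrosia artemisiifolia,anti-rodents and mosquito repellent,14,9
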