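disease	Research	research, clinical trial, clinical trials, studies being done
disease	Causes	causes, caused by, what leads to
disease	Treatment	treatment, treatments, relieve, manage, cure, remedy, therapy
disease	Prevention	prevention, prevent, how to avoid
disease	Diagnosis	diagnosis, diagnosed, exams and tests, tests for
disease	Prognosis	prognosis, life expectancy, outlook
disease	Complications	complications, possible problems
disease	Symptoms	symptoms, signs of, warning signs
disease	Inheritance	inheritance, inherited, hereditary, passed down
disease	Susceptibility	at risk, susceptibility, who gets
disease	Genetic changes	genetic changes, genes related, gene mutation
disease	Frequency	how many people are affected by, frequency, how common
disease	Considerations	considerations, what to consider
disease	Contact a medical professional	contact a medical professional, when to see a doctor, call the doctor
disease	Support Groups	support groups, where to find support, support for people
drug	Interaction with medications	interactions with medications, interact with medications, drug interactions
drug	Interaction with food	interactions with food, interaction with food
drug	Interaction with herbs and supplements	herbs and supplements
drug	Important warning	important warning, important information should i know
drug	Special instructions	special instructions, special precautions, safety concerns
drug	Brand names	brand names, brand name
drug	How does it work	how does it work, action of
drug	How effective is it	how effective
drug	Indication	why is it prescribed, indication, used to treat
drug	Contraindication	contraindication, should not take, who should not use
drug	Learn more	learn more, additional information
drug	Side effects	side effects
drug	Emergency or overdose	overdose, in case of emergency
drug	Severe reaction	severe reaction, allergic reaction
drug	Forget a dose	forget a dose, miss a dose, missed dose
drug	Dietary	dietary, special diet
drug	Why get vaccinated	why get vaccinated, vaccinated, vaccine
drug	Storage and disposal	storage, disposal, how should it be stored
drug	Usage	how should it be used, usage, how to use
drug	Dose	dose, dosage
other	Information
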